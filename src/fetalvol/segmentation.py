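"""Tri-planar (2.5D) fetal segmentation with voxel-wise vote fusion.

One shared 2D U-net classifies every slice of the isotropically resampled
volume along each of the three orthogonal axes.  The three per-voxel class
decisions are fused by majority voting: each direction casts one hard vote
(its argmax class); two or more agreeing votes win; a three-way split is
broken by the largest summed probability over the tied classes, and any
remaining tie by the lowest class index, so fusion is fully deterministic.
Training pools slices from all three axes of all training cases into a
single multi-class model, with a k-fold cross-validation harness for
hyperparameter work.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

from .image_model import (
    ClassProbabilities,
    FETUS,
    BACKGROUND,
    LabelMap,
    N_CLASSES,
    VolumeImage,
    resample_isotropic,
    resample_labels_isotropic,
    resample_labels_to_grid,
)
from .nets import UNet2D, softmax
from .quantification import dice


@dataclass
class NetConfig:
    """Architecture and training hyperparameters of the slice network.

    The network is intentionally the smallest that segments the phantom
    cohort well on a CPU; ``iso_mm`` is the isotropic grid spacing used for
    slicing during training and inference.
    """

    depth: int = 3
    base_channels: int = 8
    n_classes: int = N_CLASSES
    seed: int = 0
    epochs: int = 8
    learning_rate: float = 1e-3
    batch_size: int = 4
    slices_per_epoch: int = 240
    iso_mm: float = 1.5
    class_weighting: bool = True
    val_slices: int = 60

    def __post_init__(self) -> None:
        if self.depth < 1 or self.base_channels < 4:
            raise ValueError("depth ≥ 1 and base_channels ≥ 4 required")
        if self.n_classes != N_CLASSES:
            raise ValueError(f"n_classes must equal the label alphabet ({N_CLASSES})")


@dataclass
class FoldAssignment:
    """Cross-validation folds: per fold a (train_ids, val_ids) pair."""

    folds: list[tuple[list, list]]

    def __post_init__(self) -> None:
        all_val = [i for _, val in self.folds for i in val]
        if len(all_val) != len(set(all_val)):
            raise ValueError("an id appears in more than one validation set")
        for train, val in self.folds:
            if set(train) & set(val):
                raise ValueError("train and validation sets overlap")


def make_folds(ids, k: int, seed: int = 0) -> FoldAssignment:
    """Deterministic k-fold split with validation sets as equal as possible.

    With 20 ids and k = 4 every fold trains on 15 and validates on 5.
    """
    ids = list(ids)
    if k < 2:
        raise ValueError("k must be ≥ 2")
    if k > len(ids):
        raise ValueError(f"cannot make {k} folds from {len(ids)} ids")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    val_sets = [list(chunk) for chunk in np.array_split(np.arange(len(order)), k)]
    folds = []
    for chunk in val_sets:
        val = [order[i] for i in chunk]
        train = [i for i in order if i not in val]
        folds.append((train, val))
    return FoldAssignment(folds)


# ---------------------------------------------------------------------------
# slicing


def extract_slices(v, axis: int) -> np.ndarray:
    """Slices of a volume along one axis: (n_slices, h, w); restackable."""
    arr = v.voxels if isinstance(v, VolumeImage) else np.asarray(v)
    if axis not in (0, 1, 2):
        raise ValueError(f"axis must be 0, 1 or 2, got {axis}")
    return np.moveaxis(arr, axis, 0)


def restack(slices: np.ndarray, axis: int) -> np.ndarray:
    """Inverse of :func:`extract_slices`."""
    if axis not in (0, 1, 2):
        raise ValueError(f"axis must be 0, 1 or 2, got {axis}")
    return np.moveaxis(np.asarray(slices), 0, axis)


def _pad_hw(h, w, mult):
    ph, pw = (-h) % mult, (-w) % mult
    return (ph // 2, ph - ph // 2), (pw // 2, pw - pw // 2)


def _normalize(voxels: np.ndarray) -> np.ndarray:
    m, s = float(voxels.mean()), float(voxels.std())
    return ((voxels - m) / (s if s > 0 else 1.0)).astype(np.float32)


def predict_plane(model: UNet2D, v: VolumeImage, axis: int, batch: int = 8,
                  normalized: bool = False) -> ClassProbabilities:
    """Per-voxel class probabilities from slicing the volume along one axis.

    Slices are zero-padded symmetrically to the network's stride multiple and
    un-padded after inference, so any volume shape is accepted.
    """
    if axis not in (0, 1, 2):
        raise ValueError(f"axis must be 0, 1 or 2, got {axis}")
    vox = v.voxels if normalized else _normalize(v.voxels)
    slices = np.moveaxis(vox, axis, 0)
    s, h, w = slices.shape
    mult = 2**model.depth
    (pt, pb), (pl, pr) = _pad_hw(h, w, mult)
    padded = np.pad(slices, ((0, 0), (pt, pb), (pl, pr)))
    out = np.empty((s, h, w, model.n_classes), dtype=np.float32)
    for i in range(0, s, batch):
        logits = model.forward(padded[i : i + batch])
        probs = softmax(logits)
        out[i : i + batch] = probs[:, pt : pt + h, pl : pl + w, :]
    return ClassProbabilities(np.moveaxis(out, 0, axis))


def fuse_votes(
    p_ax: ClassProbabilities,
    p_sag: ClassProbabilities,
    p_cor: ClassProbabilities,
    spacing=(1.0, 1.0, 1.0),
    origin=(0.0, 0.0, 0.0),
) -> LabelMap:
    """Voxel-wise majority vote over the three slicing directions.

    Each direction votes with its argmax class.  Majority (≥ 2 votes) wins;
    a three-way disagreement is resolved by the largest sum of the three
    directions' probabilities over the tied classes, then by lowest class
    index.  Wherever the three argmaxes agree the result is that class,
    regardless of the probability values.
    """
    shapes = {p.spatial_shape for p in (p_ax, p_sag, p_cor)}
    if len(shapes) != 1:
        raise ValueError(f"spatial shapes differ: {shapes}")
    v1 = p_ax.argmax_labels()
    v2 = p_sag.argmax_labels()
    v3 = p_cor.argmax_labels()
    out = np.where(v1 == v2, v1, np.where(v1 == v3, v1, np.where(v2 == v3, v2, 255)))
    tied = out == 255
    if tied.any():
        total = p_ax.probs[tied] + p_sag.probs[tied] + p_cor.probs[tied]
        cand = np.sort(np.stack([v1[tied], v2[tied], v3[tied]]), axis=0)  # ascending
        scores = np.take_along_axis(total, cand.T.astype(np.intp), axis=1)
        # argmax returns the first (lowest-class) maximum
        winner = np.take_along_axis(
            cand.T, np.argmax(scores, axis=1)[:, None], axis=1
        )[:, 0]
        out[tied] = winner
    return LabelMap(out.astype(np.uint8), spacing, origin)


# ---------------------------------------------------------------------------
# training


def _case_to_slices(v: VolumeImage, l: LabelMap, iso_mm: float):
    vi = resample_isotropic(v, iso_mm, mode="linear")
    li = resample_labels_isotropic(l, iso_mm)
    vox = _normalize(vi.voxels)
    imgs, labs = [], []
    for axis in range(3):
        imgs.extend(np.moveaxis(vox, axis, 0))
        labs.extend(np.moveaxis(li.labels, axis, 0))
    return imgs, labs


def _pad_to(arr, shape, value=0):
    ph, pw = shape[0] - arr.shape[0], shape[1] - arr.shape[1]
    return np.pad(
        arr,
        ((ph // 2, ph - ph // 2), (pw // 2, pw - pw // 2)),
        constant_values=value,
    )


def _class_weights(labels_list, n_classes):
    counts = np.zeros(n_classes)
    for lab in labels_list:
        counts += np.bincount(lab.ravel(), minlength=n_classes)
    freq = counts / counts.sum()
    present = freq > 0
    w = np.ones(n_classes)
    w[present] = np.median(freq[present]) / freq[present]
    return np.clip(w, 0.25, 8.0)


def train(config: NetConfig, dataset, folds: FoldAssignment):
    """Train one model per cross-validation fold.

    ``dataset`` maps ids (list indices or a dict) to (VolumeImage, LabelMap)
    pairs.  Slices from all three axes of every training case are pooled into
    a single shared network.  Returns (models, metrics): one UNet2D per fold
    and a tidy DataFrame of per-epoch losses plus final per-class validation
    Dice rows.  Fully deterministic given config.seed.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    get = dataset.__getitem__
    for train_ids, _ in folds.folds:
        if len(train_ids) < 2:
            raise ValueError("each fold needs at least 2 training cases")

    models, rows = [], []
    for f, (train_ids, val_ids) in enumerate(folds.folds):
        rng = np.random.default_rng((config.seed, f))
        tr_imgs, tr_labs = [], []
        for i in train_ids:
            v, l = get(i)
            imgs, labs = _case_to_slices(v, l, config.iso_mm)
            tr_imgs.extend(imgs)
            tr_labs.extend(labs)
        va_imgs, va_labs = [], []
        for i in val_ids:
            v, l = get(i)
            imgs, labs = _case_to_slices(v, l, config.iso_mm)
            va_imgs.extend(imgs)
            va_labs.extend(labs)

        mult = 2**config.depth
        hmax = max(im.shape[0] for im in tr_imgs + va_imgs)
        wmax = max(im.shape[1] for im in tr_imgs + va_imgs)
        shape = (hmax + (-hmax) % mult, wmax + (-wmax) % mult)
        tr_imgs = np.stack([_pad_to(im, shape) for im in tr_imgs])
        tr_labs = np.stack([_pad_to(lb, shape) for lb in tr_labs])
        if va_imgs:
            # deterministic subsample of validation slices for loss tracking
            idx = rng.permutation(len(va_imgs))[: config.val_slices]
            va_imgs = np.stack([_pad_to(va_imgs[i], shape) for i in idx])
            va_labs = np.stack([_pad_to(va_labs[i], shape) for i in idx])

        weights = (
            _class_weights(tr_labs, config.n_classes)
            if config.class_weighting
            else np.ones(config.n_classes)
        )
        model = UNet2D(
            depth=config.depth,
            base_channels=config.base_channels,
            n_classes=config.n_classes,
            seed=int(np.random.default_rng((config.seed, f, 7)).integers(2**31)),
        )
        n_train = len(tr_imgs)
        per_epoch = min(config.slices_per_epoch, n_train)
        from .nets import weighted_cross_entropy  # local alias

        for epoch in range(config.epochs):
            order = rng.permutation(n_train)[:per_epoch]
            losses = []
            for i in range(0, per_epoch, config.batch_size):
                sel = order[i : i + config.batch_size]
                loss = model.train_step(
                    tr_imgs[sel][..., None],
                    tr_labs[sel],
                    weights,
                    lr=config.learning_rate,
                )
                losses.append(loss)
            rows.append(
                dict(fold=f, epoch=epoch, split="train", loss=float(np.mean(losses)))
            )
            if len(va_imgs):
                vl = []
                for i in range(0, len(va_imgs), config.batch_size):
                    logits = model.forward(va_imgs[i : i + config.batch_size][..., None])
                    l_, _ = weighted_cross_entropy(
                        logits, va_labs[i : i + config.batch_size], weights
                    )
                    vl.append(l_)
                rows.append(
                    dict(fold=f, epoch=epoch, split="val", loss=float(np.mean(vl)))
                )
        # final per-class Dice on the validation slice sample
        if len(va_imgs):
            preds = []
            for i in range(0, len(va_imgs), config.batch_size):
                logits = model.forward(va_imgs[i : i + config.batch_size][..., None])
                preds.append(np.argmax(logits, axis=-1))
            preds = np.concatenate(preds)
            for c in range(config.n_classes):
                rows.append(
                    dict(
                        fold=f,
                        epoch=config.epochs - 1,
                        split="val_dice",
                        loss=dice(preds == c, va_labs == c),
                        class_index=c,
                    )
                )
        models.append(model)
    return models, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# end-to-end segmentation of one volume


def segment_volume(
    model: UNet2D,
    v: VolumeImage,
    postprocess: bool = True,
    iso_mm: float = 1.5,
) -> LabelMap:
    """Full tri-planar chain on one volume.

    Resample to an isotropic grid, predict along the three axes, fuse by
    voting, resample the fused labels back to the input grid (nearest
    neighbour), and optionally keep only the largest connected component of
    the fetus class (spurious fetal islands become background).  The output
    grid always matches the input grid.
    """
    vi = resample_isotropic(v, iso_mm, mode="linear")
    vi = VolumeImage(_normalize(vi.voxels), vi.spacing, vi.origin)
    probs = [predict_plane(model, vi, axis, normalized=True) for axis in range(3)]
    fused = fuse_votes(*probs, spacing=vi.spacing, origin=vi.origin)
    out = resample_labels_to_grid(fused, v.shape, v.spacing, v.origin)
    if postprocess:
        out = keep_largest_fetal_component(out)
    return out


def keep_largest_fetal_component(l: LabelMap) -> LabelMap:
    """Relabel all but the largest connected fetal component to background.

    The fetus is a single connected body, so smaller disconnected fetal
    islands are spurious classifications.  Ties keep the first component in
    scan order (deterministic).  Other classes are untouched.
    """
    out = LabelMap(l.labels.copy(), l.spacing, l.origin, l.class_names)
    fetus = out.labels == FETUS
    cc, n = ndimage.label(fetus)
    if n > 1:
        sizes = np.bincount(cc.ravel())
        keep = sizes[1:].argmax() + 1
        out.labels[fetus & (cc != keep)] = BACKGROUND
    return out
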