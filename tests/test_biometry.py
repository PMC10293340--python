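import math

import numpy as np
import pytest
from scipy.integrate import quad

from fetalvol.biometry import (
    BiometrySet,
    hadlock_weight,
    phantom_biometry,
    ramanujan_perimeter_cm,
)
from fetalvol.phantom import PhantomSpec, generate_phantom
from fetalvol.quantification import weight_from_volume

# independent re-statements of the four log-linear expressions, evaluated
# directly; any transcription slip in the implementation shows up here
ORACLE = {
    1: lambda ac, fl, hc, bpd: 1.304 + 0.05281 * ac + 0.1938 * fl - 0.004 * ac * fl,
    2: lambda ac, fl, hc, bpd: 1.335
    - 0.0034 * ac * fl
    + 0.0316 * bpd
    + 0.0457 * ac
    + 0.1623 * fl,
    3: lambda ac, fl, hc, bpd: 1.326
    - 0.00326 * ac * fl
    + 0.0107 * hc
    + 0.0438 * ac
    + 0.158 * fl,
    4: lambda ac, fl, hc, bpd: 1.3596
    - 0.00386 * ac * fl
    + 0.0064 * hc
    + 0.00061 * bpd * ac
    + 0.0424 * ac
    + 0.174 * fl,
}


class TestHadlock:
    @pytest.mark.filterwarnings("ignore::UserWarning")
    def test_formula1_intercept(self):
        w = hadlock_weight(1, BiometrySet(AC=0.0, FL=0.0))
        assert math.log10(w.grams) == pytest.approx(1.304, abs=1e-12)

    @pytest.mark.filterwarnings("ignore::UserWarning")
    def test_formula4_intercept(self):
        w = hadlock_weight(4, BiometrySet(AC=0.0, FL=0.0, HC=0.0, BPD=0.0))
        assert math.log10(w.grams) == pytest.approx(1.3596, abs=1e-12)

    def test_formula1_worked_example(self):
        w = hadlock_weight(1, BiometrySet(AC=32.0, FL=6.5))
        expected = 10 ** (1.304 + 0.05281 * 32 + 0.1938 * 6.5 - 0.004 * 32 * 6.5)
        assert w.grams == pytest.approx(expected, rel=1e-12)
        assert w.source == "hadlock_1"

    @pytest.mark.parametrize("formula", [1, 2, 3, 4])
    def test_agrees_with_independent_oracle(self, formula, rng):
        for _ in range(50):
            ac = rng.uniform(15, 45)
            fl = rng.uniform(2, 9)
            hc = rng.uniform(15, 40)
            bpd = rng.uniform(4, 12)
            b = BiometrySet(AC=ac, FL=fl, HC=hc, BPD=bpd)
            got = hadlock_weight(formula, b).grams
            assert got == pytest.approx(
                10 ** ORACLE[formula](ac, fl, hc, bpd), rel=1e-9
            )

    @pytest.mark.parametrize(
        "formula,missing",
        [(1, "AC"), (2, "BPD"), (3, "HC"), (4, "HC")],
    )
    def test_missing_required_field_rejected(self, formula, missing):
        kwargs = dict(AC=30.0, FL=6.0, HC=32.0, BPD=9.0)
        kwargs[missing] = None
        with pytest.raises(ValueError, match=missing):
            hadlock_weight(formula, BiometrySet(**kwargs))

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            BiometrySet(AC=-1.0, FL=6.0)

    def test_out_of_range_warns_but_computes(self):
        with pytest.warns(UserWarning):
            b = BiometrySet(AC=50.0, FL=6.0)
        assert hadlock_weight(1, b).grams > 0

    @pytest.mark.parametrize("formula", [1, 2, 3, 4])
    def test_monotone_in_each_argument_over_physiological_grid(self, formula):
        ac = np.linspace(15, 45, 9)
        fl = np.linspace(2, 9, 8)
        hc = np.linspace(15, 40, 6)
        bpd = np.linspace(4, 12, 5)
        A, F, H, B = np.meshgrid(ac, fl, hc, bpd, indexing="ij")
        L = ORACLE[formula](A, F, H, B)
        used_axes = {1: (0, 1), 2: (0, 1, 3), 3: (0, 1, 2), 4: (0, 1, 2, 3)}[formula]
        for ax in used_axes:
            assert np.all(np.diff(L, axis=ax) > 0), f"not increasing along axis {ax}"


class TestPhantomBiometry:
    def test_ramanujan_exact_for_circle(self):
        r = 4.3
        assert ramanujan_perimeter_cm(r, r) == pytest.approx(2 * math.pi * r, rel=1e-12)

    def test_ramanujan_vs_quadrature(self):
        a, b = 5.0, 4.0
        e2 = 1 - (b / a) ** 2
        per, _ = quad(lambda t: 4 * a * math.sqrt(1 - e2 * math.sin(t) ** 2), 0, math.pi / 2)
        assert ramanujan_perimeter_cm(a, b) == pytest.approx(per, rel=1e-4)

    def test_femur_length_unit_conversion(self):
        spec = PhantomSpec(femur_length_mm=60.0)
        assert phantom_biometry(spec).FL == pytest.approx(6.0)

    def test_biometry_scales_linearly(self):
        b1 = phantom_biometry(PhantomSpec(fetal_scale=1.0))
        b2 = phantom_biometry(PhantomSpec(fetal_scale=1.2))
        for name in ("HC", "BPD", "AC", "FL"):
            assert getattr(b2, name) == pytest.approx(1.2 * getattr(b1, name), rel=1e-9)

    def test_hadlock_and_density_weights_rank_correlated(self):
        # across a span of fetal sizes the two estimators must order cases
        # identically, even though their absolute calibrations differ
        from scipy.stats import spearmanr

        import warnings

        from fetalvol.phantom import phantom_truth

        scales = np.linspace(0.7, 1.3, 7)
        hadlock, density = [], []
        for s in scales:
            spec = PhantomSpec(seed=1, fetal_scale=float(s))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                b = phantom_biometry(spec)
            hadlock.append(hadlock_weight(1, b).grams)
            density.append(phantom_truth(spec).fetal_weight_g)
        rho = spearmanr(hadlock, density).statistic
        assert rho == pytest.approx(1.0)
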