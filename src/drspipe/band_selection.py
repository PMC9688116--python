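"""Per-wavelength statistical wavelength selection.

At every wavelength the two class distributions (mucosa vs tumor
reflectance across sites) are first screened for normality with the
Anderson–Darling and Lilliefors tests; wavelengths where both classes
pass are compared with a pooled-variance two-sample Student t-test,
the rest with the Wilcoxon rank-sum test.  Contiguous runs of
wavelengths significant at p < alpha (default 0.001) become the selected
bands.  No multiple-testing correction is applied by default — the
selection rule is the per-wavelength threshold itself — but a Bonferroni
option exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

from .spectra import LabeledSpectraSet

__all__ = [
    "WavelengthTestResult",
    "BandSet",
    "normality_gate",
    "two_sample_test",
    "screen_wavelengths",
    "select_bands",
    "restrict_dataset",
]

_MIN_N_NORMALITY = 8


@dataclass
class WavelengthTestResult:
    """Per-wavelength test decisions and p-values on one grid."""

    wavelengths: np.ndarray
    p_values: np.ndarray
    test_used: np.ndarray          # "t" | "wilcoxon"
    normal: np.ndarray             # bool: both classes passed the gate
    ad_reject: np.ndarray          # (n_wl, 2) per class
    lilliefors_reject: np.ndarray  # (n_wl, 2) per class

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "wavelength": self.wavelengths,
            "p_value": self.p_values,
            "test_used": self.test_used,
            "normal": self.normal,
            "ad_reject_mucosa": self.ad_reject[:, 0],
            "ad_reject_tumor": self.ad_reject[:, 1],
            "lilliefors_reject_mucosa": self.lilliefors_reject[:, 0],
            "lilliefors_reject_tumor": self.lilliefors_reject[:, 1],
        })


@dataclass
class BandSet:
    """Ordered, disjoint wavelength intervals selected by the tests."""

    intervals: list = field(default_factory=list)  # [(lo, hi), ...] in nm
    alpha: float = 0.001

    def __post_init__(self) -> None:
        ivs = [(float(lo), float(hi)) for lo, hi in self.intervals]
        ivs.sort()
        for (lo, hi) in ivs:
            if lo > hi:
                raise ValueError(f"interval ({lo}, {hi}) has lo > hi")
        for (a, b), (c, _) in zip(ivs, ivs[1:]):
            if c <= b:
                raise ValueError("intervals must be disjoint")
        self.intervals = ivs

    def __len__(self) -> int:
        return len(self.intervals)

    def mask(self, wavelengths: np.ndarray) -> np.ndarray:
        wl = np.asarray(wavelengths, dtype=float)
        m = np.zeros(wl.shape, dtype=bool)
        for lo, hi in self.intervals:
            m |= (wl >= lo) & (wl <= hi)
        return m

    def covers(self, lo: float, hi: float) -> bool:
        """True if some single interval contains [lo, hi] entirely."""
        return any(a <= lo and hi <= b for a, b in self.intervals)

    def to_json(self) -> list:
        return [[lo, hi] for lo, hi in self.intervals]

    @classmethod
    def from_json(cls, data, alpha: float = 0.001) -> "BandSet":
        return cls(intervals=[(lo, hi) for lo, hi in data], alpha=alpha)


def _ad_rejects(x: np.ndarray, alpha: float) -> bool:
    try:
        res = stats.anderson(x, dist="norm", method="interpolate")
        return bool(res.pvalue < alpha)
    except TypeError:  # older scipy: tabulated critical values
        res = stats.anderson(x, dist="norm")
        sig = np.asarray(res.significance_level) / 100.0
        idx = int(np.argmin(np.abs(sig - alpha)))
        return bool(res.statistic > res.critical_values[idx])


def _lilliefors_rejects(x: np.ndarray, alpha: float) -> bool:
    _, p = lilliefors(x, dist="norm", pvalmethod="table")
    return bool(p < alpha)


def normality_gate(group_a: np.ndarray, group_b: np.ndarray,
                   alpha_norm: float = 0.05) -> dict:
    """Screen both class samples at one wavelength for normality.

    Returns a dict with the overall decision (``normal`` is True only if
    neither Anderson–Darling nor Lilliefors rejects in either class) and
    the individual per-test, per-class rejections.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    for g in (a, b):
        if g.size < _MIN_N_NORMALITY:
            raise ValueError(
                f"normality tests need n >= {_MIN_N_NORMALITY} per class, got {g.size}"
            )
    ad = (_ad_rejects(a, alpha_norm), _ad_rejects(b, alpha_norm))
    lf = (_lilliefors_rejects(a, alpha_norm), _lilliefors_rejects(b, alpha_norm))
    return {"normal": not (any(ad) or any(lf)), "ad_reject": ad, "lilliefors_reject": lf}


def two_sample_test(group_a: np.ndarray, group_b: np.ndarray,
                    normal: bool = True) -> float:
    """Two-sided comparison of the class distributions at one wavelength.

    Pooled-variance Student t-test when the normality gate passed,
    Wilcoxon rank-sum otherwise (exact for small samples without ties,
    normal approximation with tie correction for larger ones).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("groups must be finite")
    if normal:
        if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
            return 1.0 if a.mean() == b.mean() else 0.0
        _, p = stats.ttest_ind(a, b, equal_var=True)
        return float(p)
    small = max(a.size, b.size) <= 20
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (small and not has_ties) else "asymptotic"
    _, p = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(p)


def screen_wavelengths(dataset: LabeledSpectraSet,
                         alpha_norm: float = 0.05) -> WavelengthTestResult:
    """Run the normality gate and two-sample test at every wavelength."""
    dataset.require_both_classes()
    A = dataset.spectra[dataset.class_mask("mucosa")]
    B = dataset.spectra[dataset.class_mask("tumor")]
    n_wl = dataset.wavelengths.size
    p_values = np.empty(n_wl)
    test_used = np.empty(n_wl, dtype=object)
    normal = np.empty(n_wl, dtype=bool)
    ad = np.empty((n_wl, 2), dtype=bool)
    lf = np.empty((n_wl, 2), dtype=bool)
    for j in range(n_wl):
        gate = normality_gate(A[:, j], B[:, j], alpha_norm)
        normal[j] = gate["normal"]
        ad[j] = gate["ad_reject"]
        lf[j] = gate["lilliefors_reject"]
        test_used[j] = "t" if gate["normal"] else "wilcoxon"
        p_values[j] = two_sample_test(A[:, j], B[:, j], normal=gate["normal"])
    return WavelengthTestResult(dataset.wavelengths.copy(), p_values,
                                test_used, normal, ad, lf)


def select_bands(result: WavelengthTestResult | None = None,
                 alpha: float = 0.001, min_run: int = 3, max_gap: int = 0,
                 *, p_values: np.ndarray | None = None,
                 wavelengths: np.ndarray | None = None,
                 bonferroni: bool = False) -> BandSet:
    """Extract maximal contiguous significant wavelength runs as bands.

    Runs of grid points with p < alpha separated by gaps of at most
    ``max_gap`` points are merged, then runs shorter than ``min_run``
    points are dropped.  ``bonferroni=True`` divides alpha by the number
    of wavelengths first (off by default).
    """
    if result is not None:
        p_values = result.p_values
        wavelengths = result.wavelengths
    if p_values is None or wavelengths is None:
        raise ValueError("provide a WavelengthTestResult or p_values + wavelengths")
    p = np.asarray(p_values, dtype=float)
    wl = np.asarray(wavelengths, dtype=float)
    threshold = alpha / p.size if bonferroni else alpha
    sig = p < threshold

    runs: list[list[int]] = []
    idx = np.flatnonzero(sig)
    for i in idx:
        if runs and i - runs[-1][-1] <= max_gap + 1:
            runs[-1].append(i)
        else:
            runs.append([i])
    intervals = [(wl[r[0]], wl[r[-1]]) for r in runs if len(r) >= min_run]
    return BandSet(intervals=intervals, alpha=alpha)


def restrict_dataset(dataset: LabeledSpectraSet, bands: BandSet) -> LabeledSpectraSet:
    """Keep only the wavelength columns falling inside the given bands."""
    mask = bands.mask(dataset.wavelengths)
    if not mask.any():
        raise ValueError("bands do not intersect the dataset's wavelength grid")
    return LabeledSpectraSet(
        spectra=dataset.spectra[:, mask],
        wavelengths=dataset.wavelengths[mask],
        labels=dataset.labels.copy(),
        patient_ids=dataset.patient_ids.copy(),
        probe=dataset.probe,
    )
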