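"""DNA ploidy diagnosis from per-nucleus IOD tables.

The diagnostic chain is the one used in clinical image cytometry of oral
epithelial lesions:

1. **Normalisation.** Internal control cells (lymphocytes, fibroblasts) in
   the same preparation carry normal 2c DNA; the modal control IOD defines
   the scale, and every retained epithelial nucleus's DNA content is
   expressed in c units (``c = iod * normalization_factor``).
2. **Stemline peak detection.** A kernel-smoothed density over the c-value
   histogram; a stemline peak is a narrow local mode to which more than 10%
   of the epithelial nuclei are assigned.  A peak's diploid index (DI) is
   its mode divided by 2 (normal G1 -> DI 1.0, G2 -> DI 2.0).
3. **Rule cascade.**

   * *inadequate* — fewer than 300 retained epithelial nuclei, or the
     diploid-peak coefficient of variation exceeds 5% (QC failure), or no
     interpretable stemline structure;
   * *aneuploid* — a supra-threshold peak with DI outside both the diploid
     window [0.9, 1.1] and the G2 window [1.8, 2.2], **or** more than 1% of
     epithelial nuclei above 5c (the 5c exceeding rate);
   * *tetraploid* — a supra-threshold 4c peak (DI in [1.9, 2.1]) with no
     other abnormality;
   * *diploid* — exactly one G0/G1 peak, a 4c-band fraction of at most 10%
     and a 5c exceeding rate of at most 1%.

Thresholds are strict inequalities throughout; ties fall to the less
abnormal side.  All rule identifiers that fired are recorded in the
diagnosis for auditability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal, stats

from .exceptions import InadequateSampleError
from .nuclei import NucleusRecord

__all__ = [
    "DIHistogram",
    "StemlinePeak",
    "PloidyDiagnosis",
    "normalize_to_c",
    "detect_peaks",
    "exceeding_rate",
    "diploid_peak_cv",
    "classify_ploidy",
]

DIPLOID_DI_WINDOW = (0.9, 1.1)
G2_DI_WINDOW = (1.8, 2.2)
TETRAPLOID_DI_WINDOW = (1.9, 2.1)
MIN_EPITHELIAL_NUCLEI = 300
MAX_DIPLOID_CV_PCT = 5.0
MIN_PEAK_FRACTION = 0.10
FIVE_C_RATE_LIMIT = 0.01
MIN_CONTROL_NUCLEI = 30


@dataclass
class DIHistogram:
    """Normalised DNA-content histogram of one sample.

    ``c_values`` holds the DNA content (c units, 2c = normal G0/G1) of every
    retained epithelial nucleus; controls, debris and artifact-flagged nuclei
    are excluded before normalisation.
    """

    sample_id: str
    c_values: np.ndarray
    n_controls_used: int
    normalization_factor: float

    def __post_init__(self) -> None:
        self.c_values = np.asarray(self.c_values, dtype=float)


@dataclass
class StemlinePeak:
    """A detected stemline peak with its assigned-nucleus statistics."""

    mode_c: float
    di: float
    fraction: float
    cv_pct: float
    n_assigned: int = 0
    # c-values assigned to this mode; kept for downstream QC, not serialised
    assigned_c: np.ndarray | None = field(default=None, repr=False, compare=False)


@dataclass
class PloidyDiagnosis:
    """Output of the diagnostic rule cascade."""

    sample_id: str
    label: str
    peaks: list[StemlinePeak]
    diploid_peak_cv_pct: float
    four_c_fraction: float
    five_c_exceeding_rate: float
    nine_c_exceeding_rate: float
    n_epithelial_retained: int
    qc_pass: bool
    reasons: list[str]
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "label": self.label,
            "peaks": [
                {"mode_c": p.mode_c, "di": p.di, "fraction": p.fraction,
                 "cv_pct": p.cv_pct, "n_assigned": p.n_assigned}
                for p in self.peaks
            ],
            "diploid_peak_cv_pct": self.diploid_peak_cv_pct,
            "four_c_fraction": self.four_c_fraction,
            "five_c_exceeding_rate": self.five_c_exceeding_rate,
            "nine_c_exceeding_rate": self.nine_c_exceeding_rate,
            "n_epithelial_retained": self.n_epithelial_retained,
            "qc_pass": self.qc_pass,
            "reasons": self.reasons,
            "params": self.params,
        }


def normalize_to_c(records: Sequence[NucleusRecord]) -> DIHistogram:
    """Normalise epithelial IODs against the internal diploid controls.

    The 2c reference is the trimmed mean IOD of the modal control cluster
    (controls within ±25% of the kernel-density mode, 5% trimmed mean), which
    is robust to stray debris misclassified as control.  Requires at least
    30 artifact-free control nuclei.
    """
    records = list(records)
    sample_ids = {r.sample_id for r in records}
    sid = records[0].sample_id if records else "sample"
    if len(sample_ids) > 1:
        raise ValueError(f"records span multiple samples: {sorted(sample_ids)}")

    iods = np.array([r.iod for r in records], dtype=float)
    if np.any(iods <= 0):
        raise ValueError("all IODs must be strictly positive for normalisation")

    ctrl = np.array([r.iod for r in records
                     if r.cls in ("lymphocyte", "fibroblast") and r.artifact == "none"])
    if len(ctrl) < MIN_CONTROL_NUCLEI:
        raise InadequateSampleError(
            f"{sid}: only {len(ctrl)} control nuclei; "
            f"at least {MIN_CONTROL_NUCLEI} required for normalisation")

    if np.ptp(ctrl) < 1e-12 * ctrl.mean():
        ref = float(ctrl.mean())
    else:
        kde = stats.gaussian_kde(ctrl)
        grid = np.linspace(ctrl.min(), ctrl.max(), 512)
        mode = grid[int(np.argmax(kde(grid)))]
        cluster = ctrl[(ctrl >= 0.75 * mode) & (ctrl <= 1.25 * mode)]
        if len(cluster) < MIN_CONTROL_NUCLEI // 2:
            cluster = ctrl
        ref = float(stats.trim_mean(cluster, 0.05))

    factor = 2.0 / ref
    epi = np.array([r.iod for r in records
                    if r.cls == "epithelial" and r.artifact == "none"])
    return DIHistogram(sid, epi * factor, int(len(ctrl)), factor)


def _silverman_bandwidth(c: np.ndarray, floor: float) -> float:
    sd = float(np.std(c, ddof=1)) if len(c) > 1 else 0.0
    iqr = float(np.subtract(*np.percentile(c, [75, 25])))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        return floor
    return max(floor, 0.9 * spread * len(c) ** (-0.2))


def detect_peaks(hist: DIHistogram,
                 min_fraction: float = MIN_PEAK_FRACTION,
                 bandwidth_floor: float = 0.05,
                 assign_window: float = 0.10,
                 max_rel_fwhm: float = 0.4,
                 prominence_rel: float = 0.05) -> list[StemlinePeak]:
    """Detect stemline peaks in a c-value histogram.

    Local maxima of a Gaussian-kernel density (Silverman bandwidth with an
    absolute floor of ``bandwidth_floor`` c) are candidate modes; modes must
    be prominent (``prominence_rel`` of the maximum density) and narrow
    (full width at half maximum at most ``max_rel_fwhm`` times the mode
    position — diagnostic stemline peaks are narrow by the CV QC gate, and
    the width gate rejects broad plateaus that are not peaks).  Each nucleus
    is assigned to the nearest surviving mode if within ±``assign_window``
    of it (relative); peaks whose assigned fraction exceeds ``min_fraction``
    are returned sorted by position.  Fractions need not sum to 1 — S-phase
    and scatter stay unassigned.
    """
    c = np.asarray(hist.c_values, dtype=float)
    if len(c) == 0:
        raise ValueError("empty histogram: no retained epithelial nuclei")

    if np.ptp(c) < 1e-12:  # degenerate: all nuclei identical
        mode = float(c[0])
        return [StemlinePeak(mode, mode / 2.0, 1.0, 0.0, len(c), c.copy())]

    bw = _silverman_bandwidth(c, bandwidth_floor)
    kde = stats.gaussian_kde(c, bw_method=bw / float(np.std(c, ddof=1)))
    lo = max(0.0, c.min() - 3 * bw)
    hi = c.max() + 3 * bw
    grid = np.linspace(lo, hi, 2048)
    dens = kde(grid)

    idx, _ = signal.find_peaks(dens, prominence=prominence_rel * dens.max())
    if len(idx) == 0:
        return []
    step = grid[1] - grid[0]

    def _half_height_width(i: int) -> float:
        # width where the density falls below half the peak's absolute
        # height; unlike a prominence-relative width this stays wide for a
        # shallow bump riding on a plateau
        half = dens[i] / 2.0
        left = i
        while left > 0 and dens[left] > half:
            left -= 1
        right = i
        while right < len(dens) - 1 and dens[right] > half:
            right += 1
        return (right - left) * step

    modes = np.array([grid[i] for i in idx
                      if _half_height_width(i) <= max_rel_fwhm * max(grid[i], 1e-9)])
    if len(modes) == 0:
        return []

    # nearest-mode assignment within a relative window
    d = np.abs(c[:, None] - modes[None, :])
    nearest = np.argmin(d, axis=1)
    within = d[np.arange(len(c)), nearest] <= assign_window * modes[nearest]

    peaks: list[StemlinePeak] = []
    for j, mode in enumerate(modes):
        assigned = c[(nearest == j) & within]
        if len(assigned) == 0:
            continue
        frac = len(assigned) / len(c)
        if len(assigned) > 1:
            cv = 100.0 * float(np.std(assigned, ddof=1) / np.mean(assigned))
        else:
            cv = 0.0
        peaks.append(StemlinePeak(float(mode), float(mode) / 2.0, frac, cv,
                                  len(assigned), assigned))
    peaks = [p for p in peaks if p.fraction > min_fraction]
    peaks.sort(key=lambda p: p.mode_c)
    return peaks


def exceeding_rate(hist: DIHistogram, threshold_c: float) -> float:
    """Fraction of retained epithelial nuclei with DNA content above
    ``threshold_c`` (strict inequality, exact count)."""
    if threshold_c <= 0:
        raise ValueError(f"threshold_c must be positive, got {threshold_c}")
    c = np.asarray(hist.c_values)
    if len(c) == 0:
        return 0.0
    return float(np.count_nonzero(c > threshold_c)) / len(c)


def diploid_peak_cv(hist: DIHistogram, peaks: Sequence[StemlinePeak]
                    ) -> tuple[float, bool]:
    """CV (%) of the diploid peak: SD/mean of the c-values assigned to the
    peak with DI in [0.9, 1.1].

    When no such peak exists (a pure aneuploid shift) the CV of the largest
    peak is returned with the flag set, as the QC question — are peaks narrow
    enough to discriminate — still applies.
    Returns ``(cv_pct, used_fallback_peak)``.
    """
    if not peaks:
        return float("nan"), True
    lo, hi = DIPLOID_DI_WINDOW
    diploid = [p for p in peaks if lo <= p.di <= hi]
    if diploid:
        best = max(diploid, key=lambda p: p.fraction)
        return best.cv_pct, False
    best = max(peaks, key=lambda p: p.fraction)
    return best.cv_pct, True


def _four_c_fraction(c: np.ndarray) -> float:
    if len(c) == 0:
        return 0.0
    lo = 2 * G2_DI_WINDOW[0]  # 3.6c
    hi = 2 * G2_DI_WINDOW[1]  # 4.4c
    return float(np.count_nonzero((c >= lo) & (c <= hi))) / len(c)


def classify_ploidy(hist: DIHistogram,
                    min_nuclei: int = MIN_EPITHELIAL_NUCLEI,
                    max_cv_pct: float = MAX_DIPLOID_CV_PCT,
                    min_peak_fraction: float = MIN_PEAK_FRACTION,
                    **peak_kwargs) -> PloidyDiagnosis:
    """Apply the diagnostic rule cascade to a normalised histogram.

    See the module docstring for the rules.  Every fired rule is recorded in
    ``reasons``; QC failures yield ``label='inadequate'`` with
    ``qc_pass=False``.
    """
    c = np.asarray(hist.c_values, dtype=float)
    n = len(c)
    peaks = detect_peaks(hist, min_fraction=min_peak_fraction, **peak_kwargs) if n else []
    four_c = _four_c_fraction(c)
    fer = exceeding_rate(hist, 5.0) if n else 0.0
    ner = exceeding_rate(hist, 9.0) if n else 0.0
    cv, cv_fallback = diploid_peak_cv(hist, peaks)

    reasons: list[str] = []
    if cv_fallback:
        reasons.append("cv_from_largest_peak")
    params = {
        "min_nuclei": min_nuclei,
        "max_cv_pct": max_cv_pct,
        "min_peak_fraction": min_peak_fraction,
        "bandwidth_floor_c": peak_kwargs.get("bandwidth_floor", 0.05),
        "assign_window_rel": peak_kwargs.get("assign_window", 0.10),
    }

    def diag(label: str, qc: bool) -> PloidyDiagnosis:
        return PloidyDiagnosis(hist.sample_id, label, peaks, cv, four_c, fer,
                               ner, n, qc, reasons, params)

    # rule 1: adequacy / QC
    if n < min_nuclei:
        reasons.append("too_few_epithelial_nuclei")
        return diag("inadequate", False)
    if np.isfinite(cv) and cv > max_cv_pct:
        reasons.append("diploid_peak_cv_gt_5pct")
        return diag("inadequate", False)

    dlo, dhi = DIPLOID_DI_WINDOW
    glo, ghi = G2_DI_WINDOW
    tlo, thi = TETRAPLOID_DI_WINDOW

    # rule 2: aneuploid — abnormal stemline peak or >5c excess
    abnormal = [p for p in peaks
                if not (dlo <= p.di <= dhi) and not (glo <= p.di <= ghi)]
    if abnormal:
        reasons.append("abnormal_stemline_peak")
    if fer > FIVE_C_RATE_LIMIT:
        reasons.append("five_c_rate_gt_1pct")
    if abnormal or fer > FIVE_C_RATE_LIMIT:
        return diag("aneuploid", True)

    # rule 3: tetraploid — supra-threshold 4c peak, no other abnormality
    tetra = [p for p in peaks if tlo <= p.di <= thi]
    gap = [p for p in peaks if (glo <= p.di <= ghi) and not (tlo <= p.di <= thi)]
    if tetra:
        reasons.append("four_c_peak_gt_10pct")
        return diag("tetraploid", True)
    if gap:
        # printed criteria leave DI in [1.8,2.2] \ [1.9,2.1] unassigned: the
        # G2 exemption marks the band non-aneuploid, so call it tetraploid
        reasons.append("four_c_peak_gt_10pct")
        reasons.append("rule_gap_g2_band_peak")
        return diag("tetraploid", True)

    # rule 4: diploid — one G1 peak, quiet 4c band, quiet >5c tail
    g1 = [p for p in peaks if dlo <= p.di <= dhi]
    if len(g1) == 1 and four_c <= MIN_PEAK_FRACTION:
        reasons.append("single_g1_peak")
        return diag("diploid", True)

    if len(g1) == 1 and four_c > MIN_PEAK_FRACTION:
        # 4c band over 10% without a discrete 4c mode: treat as the
        # tetraploid criterion's target population
        reasons.append("four_c_band_gt_10pct_no_peak")
        return diag("tetraploid", True)

    # no or ambiguous G1 structure: the histogram is not interpretable
    reasons.append("no_single_g1_peak" if not g1 else "multiple_g1_peaks")
    return diag("inadequate", False)
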