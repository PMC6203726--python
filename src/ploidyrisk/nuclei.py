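"""Synthetic per-nucleus Feulgen densitometry tables.

DNA image cytometry measures, for every nucleus on a stained monolayer, the
integrated optical density (IOD), which is proportional to nuclear DNA
content.  Nuclei are machine-classified into epithelial cells, internal
control cells (lymphocytes and fibroblasts, which carry normal 2c DNA and
define the measurement scale) and debris, and gallery editing discards cut,
overlapped and pyknotic nuclei.  This module generates measurement tables
with exactly that structure from a known ground truth, so the diagnostic
classifier can be validated against the generating components.

The generative model:

* every stemline (clonal epithelial population) with DNA index ``di``
  contributes a G0/G1 peak at ``c = 2*di``, a G2 peak at ``c = 4*di`` and a
  uniform S-phase plateau between them; peaks are Gaussian in IOD with
  SD = CV x mean,
* internal controls sit at 2c with their own small CV,
* an optional fraction of epithelial nuclei is placed uniformly on
  c in (5, 9] to emulate rare supra-tetraploid events,
* debris is sub-1c, and artifact nuclei carry distorted IODs
  (cut: halved, overlapped: doubled, pyknotic: compressed spread).

All randomness flows from ``SampleSimConfig.seed``; the same config always
yields the same table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError, ParseError

__all__ = [
    "NUCLEUS_CLASSES",
    "ARTIFACT_TYPES",
    "Stemline",
    "SampleSimConfig",
    "NucleusRecord",
    "simulate_sample",
    "write_nuclei_table",
    "read_nuclei_table",
]

NUCLEUS_CLASSES = ("epithelial", "lymphocyte", "fibroblast", "debris")
ARTIFACT_TYPES = ("none", "cut", "overlapped", "pyknotic")


@dataclass(frozen=True)
class Stemline:
    """One clonal epithelial population.

    Parameters
    ----------
    di : float
        DNA index of the G1 peak (1.0 = normal diploid; the G1 peak sits at
        ``c = 2*di``).
    fraction : float
        Share of epithelial nuclei belonging to this stemline (fractions of
        all stemlines are renormalised over their sum).
    g2_fraction, s_fraction : float
        Within-stemline shares of cycling nuclei at G2 (``c = 4*di``) and on
        the S-phase plateau between G1 and G2.
    """

    di: float
    fraction: float
    g2_fraction: float = 0.05
    s_fraction: float = 0.05


@dataclass
class SampleSimConfig:
    """Configuration of one simulated cytometry sample.

    ``iod_scale`` is the arbitrary densitometric unit per 1c of DNA, so the
    normal diploid G1 peak lies at ``2 * iod_scale``.  Class fractions must
    sum to <= 1; any remainder is assigned to the epithelial class.
    """

    seed: int = 0
    n_total: int = 3000
    epithelial_fraction: float = 0.60
    control_fraction: float = 0.25
    debris_fraction: float = 0.10
    artifact_fraction: float = 0.05
    diploid_cv_pct: float = 2.5
    control_cv_pct: float = 2.0
    stemlines: Sequence[Stemline] = field(
        default_factory=lambda: (Stemline(1.0, 1.0),)
    )
    five_c_excess_fraction: float = 0.0
    iod_scale: float = 50.0

    def __post_init__(self) -> None:
        self.stemlines = tuple(
            s if isinstance(s, Stemline) else Stemline(*s) for s in self.stemlines
        )
        self.validate()

    def validate(self) -> None:
        if self.n_total < 1:
            raise ConfigError(f"n_total must be >= 1, got {self.n_total}")
        for name in ("epithelial_fraction", "control_fraction",
                     "debris_fraction", "artifact_fraction",
                     "five_c_excess_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        class_sum = (self.epithelial_fraction + self.control_fraction
                     + self.debris_fraction + self.artifact_fraction)
        if class_sum > 1.0 + 1e-9:
            raise ConfigError(
                f"class fractions sum to {class_sum:.4f} > 1 "
                "(epithelial/control/debris/artifact)")
        if not 1.0 <= self.diploid_cv_pct <= 5.0:
            raise ConfigError(
                f"diploid_cv_pct must lie in [1, 5], got {self.diploid_cv_pct}")
        if self.control_cv_pct <= 0:
            raise ConfigError("control_cv_pct must be positive")
        if self.iod_scale <= 0:
            raise ConfigError(f"iod_scale must be positive, got {self.iod_scale}")
        if not self.stemlines:
            raise ConfigError("stemlines must contain at least one stemline")
        frac_sum = 0.0
        for i, s in enumerate(self.stemlines):
            if s.di <= 0:
                raise ConfigError(f"stemlines[{i}].di must be > 0, got {s.di}")
            if not 0.0 < s.fraction <= 1.0:
                raise ConfigError(
                    f"stemlines[{i}].fraction must lie in (0, 1], got {s.fraction}")
            if s.g2_fraction < 0 or s.s_fraction < 0 or s.g2_fraction + s.s_fraction >= 1:
                raise ConfigError(
                    f"stemlines[{i}] g2_fraction + s_fraction must lie in [0, 1)")
            frac_sum += s.fraction
        if frac_sum > 1.0 + 1e-9:
            raise ConfigError(f"stemline fractions sum to {frac_sum:.4f} > 1")


@dataclass(frozen=True)
class NucleusRecord:
    """One measured nucleus.

    ``truth_component`` names the generating mixture component and is only
    ever emitted by the simulator; the classifier never reads it.
    """

    sample_id: str
    iod: float
    cls: str
    artifact: str = "none"
    truth_component: str | None = None


def _allocate(n: int, fractions: Sequence[float]) -> list[int]:
    """Integer counts summing to ``n``, proportional to ``fractions``.

    Largest-remainder apportionment; deterministic (remainder ties broken by
    position).
    """
    fractions = np.asarray(fractions, dtype=float)
    total = fractions.sum()
    if total <= 0:
        out = [0] * len(fractions)
        out[0] = n
        return out
    target = fractions / total * n
    base = np.floor(target).astype(int)
    short = n - int(base.sum())
    order = np.argsort(-(target - base), kind="stable")
    for j in order[:short]:
        base[j] += 1
    return base.tolist()


def _gaussian(rng: np.random.Generator, mean: float, cv_pct: float, n: int) -> np.ndarray:
    iod = rng.normal(mean, cv_pct / 100.0 * mean, size=n)
    # CV <= 5% keeps mass ~20 SDs from zero; clip guards pathological draws
    return np.maximum(iod, 1e-9)


def simulate_sample(config: SampleSimConfig, sample_id: str | None = None
                    ) -> list[NucleusRecord]:
    """Generate one per-nucleus IOD table.

    Deterministic given ``config.seed``.  Returns records in a fixed layout
    (stemline nuclei, >5c events, controls, debris, artifacts); downstream
    analysis is order-invariant.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    sid = sample_id if sample_id is not None else f"sim{config.seed}"
    scale = config.iod_scale

    leftover = max(0.0, 1.0 - (config.epithelial_fraction + config.control_fraction
                               + config.debris_fraction + config.artifact_fraction))
    n_epi, n_ctrl, n_debris, n_art = _allocate(
        config.n_total,
        [config.epithelial_fraction + leftover, config.control_fraction,
         config.debris_fraction, config.artifact_fraction])

    records: list[NucleusRecord] = []

    # --- epithelial: stemlines plus the >5c excess component
    n_5c, n_stem_total = _allocate(
        n_epi, [config.five_c_excess_fraction, 1.0 - config.five_c_excess_fraction])
    stem_counts = _allocate(n_stem_total, [s.fraction for s in config.stemlines])
    for i, (stem, n_s) in enumerate(zip(config.stemlines, stem_counts)):
        label = f"stemline{i}"
        n_g2, n_sphase, n_g1 = _allocate(
            n_s, [stem.g2_fraction, stem.s_fraction,
                  1.0 - stem.g2_fraction - stem.s_fraction])
        g1_mean = 2.0 * stem.di * scale
        g2_mean = 4.0 * stem.di * scale
        for iod in _gaussian(rng, g1_mean, config.diploid_cv_pct, n_g1):
            records.append(NucleusRecord(sid, float(iod), "epithelial", "none", label))
        for iod in rng.uniform(g1_mean, g2_mean, size=n_sphase):
            records.append(NucleusRecord(sid, float(iod), "epithelial", "none", label))
        for iod in _gaussian(rng, g2_mean, config.diploid_cv_pct, n_g2):
            records.append(NucleusRecord(sid, float(iod), "epithelial", "none", label))
    for iod in rng.uniform(5.0 * scale, 9.0 * scale, size=n_5c):
        records.append(NucleusRecord(sid, float(iod), "epithelial", "none",
                                     "five_c_excess"))

    # --- internal controls at 2c (lymphocytes and fibroblasts share one
    # distribution; their counts differ by preparation method in real data
    # but their DNA content does not)
    n_lym, n_fib = _allocate(n_ctrl, [0.5, 0.5])
    for cls, n_c in (("lymphocyte", n_lym), ("fibroblast", n_fib)):
        for iod in _gaussian(rng, 2.0 * scale, config.control_cv_pct, n_c):
            records.append(NucleusRecord(sid, float(iod), cls, "none", "control"))

    # --- debris: sub-1c fragments
    for iod in rng.uniform(1e-9, 0.8 * scale, size=n_debris):
        records.append(NucleusRecord(sid, float(iod), "debris", "none", "debris"))

    # --- artifacts: epithelial-like nuclei with distorted IOD
    counts = _allocate(n_art, [1, 1, 1])
    base_mean = 2.0 * config.stemlines[0].di * scale
    for kind, n_k in zip(("cut", "overlapped", "pyknotic"), counts):
        base = _gaussian(rng, base_mean, config.diploid_cv_pct, n_k)
        if kind == "cut":
            iods = base * 0.5
        elif kind == "overlapped":
            iods = base * 2.0
        else:  # pyknotic: condensed chromatin -> compressed spread
            iods = base_mean + (base - base_mean) * 0.2
        for iod in iods:
            records.append(NucleusRecord(sid, float(iod), "epithelial", kind,
                                         f"artifact_{kind}"))

    return records


# ---------------------------------------------------------------------------
# Table I/O.  Plain CSV with header `sample_id,iod,cls,artifact` plus an
# optional `truth_component` column (written only when present).

_REQUIRED_COLS = ["sample_id", "iod", "cls", "artifact"]


def write_nuclei_table(records: Iterable[NucleusRecord], path: str | Path) -> None:
    records = list(records)
    has_truth = any(r.truth_component is not None for r in records)
    cols = _REQUIRED_COLS + (["truth_component"] if has_truth else [])
    rows = []
    for r in records:
        row = {"sample_id": r.sample_id, "iod": r.iod, "cls": r.cls,
               "artifact": r.artifact}
        if has_truth:
            row["truth_component"] = "" if r.truth_component is None else r.truth_component
        rows.append(row)
    # %.17g round-trips float64 exactly
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False, float_format="%.17g")


def read_nuclei_table(path: str | Path) -> list[NucleusRecord]:
    """Read a nuclei CSV, validating each row.

    Raises :class:`ParseError` naming the file line (header = line 1) for
    malformed rows: negative IOD, unknown class or artifact label.
    """
    try:
        df = pd.read_csv(path, dtype={"sample_id": str},
                         float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 - rewrap for a uniform error type
        raise ParseError(f"{path}: cannot parse nuclei table: {exc}") from exc
    missing = [c for c in _REQUIRED_COLS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    has_truth = "truth_component" in df.columns
    out: list[NucleusRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        iod = getattr(row, "iod")
        try:
            iod = float(iod)
        except (TypeError, ValueError):
            raise ParseError(f"{path}, line {line}: iod {iod!r} is not a number")
        if not np.isfinite(iod) or iod < 0:
            raise ParseError(f"{path}, line {line}: iod must be >= 0, got {iod}")
        cls = getattr(row, "cls")
        if cls not in NUCLEUS_CLASSES:
            raise ParseError(f"{path}, line {line}: unknown nucleus class {cls!r}")
        artifact = getattr(row, "artifact")
        if artifact not in ARTIFACT_TYPES:
            raise ParseError(f"{path}, line {line}: unknown artifact flag {artifact!r}")
        truth = None
        if has_truth:
            t = getattr(row, "truth_component")
            if isinstance(t, str) and t:
                truth = t
            elif t is not None and not (isinstance(t, float) and np.isnan(t)):
                truth = str(t)
        out.append(NucleusRecord(str(getattr(row, "sample_id")), iod, cls,
                                 artifact, truth))
    return out
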