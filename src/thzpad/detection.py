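"""Two-criteria fingerprint spoof detection and TDR/FDR evaluation.

Criterion 1 (time domain): the q-coefficient, the ratio of the two local
minima flanking the main-pulse maximum.  Positive-phase reflections (all
Group I overlays, whose index is below the window's) have a deep trailing
undershoot, q > 0.85; negative-phase signals (fingers and the water-rich
Group II) have their deep minimum before the rebound maximum, q well
below 0.5.

Criterion 2 (frequency domain): five reflectance feature points in the
0.18-1.5 THz range and four ratios fq1..fq4, thresholded to separate the
steeply falling, wide-minimum Group II reflectance from the
minimum-then-ascending genuine-finger reflectance.  A sample is flagged
as a spoof when criterion 1 fires, or, failing that, when all four
frequency coefficients pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .signals import ReflectanceSpectrum, TimeTrace, reflectance

__all__ = [
    "DegenerateSignalError",
    "Thresholds",
    "QFeatures",
    "FrequencyFeatures",
    "DetectionResult",
    "q_coefficient",
    "frequency_features",
    "classify",
    "EvaluationReport",
    "evaluate",
]


class DegenerateSignalError(ValueError):
    """Raised when a trace or spectrum cannot support feature extraction."""


@dataclass(frozen=True)
class Thresholds:
    """Decision thresholds and search windows of the two-criteria algorithm."""

    q_thr: float = 0.85
    fq1_thr: float = 4.5
    fq2_thr: float = 3.5
    fq3_thr: float = 1.21
    fq4_thr: float = 1.1
    search_window_ps: tuple[float, float] = (9.0, 11.0)
    vicinity_ps: float = 2.0

    def __post_init__(self):
        for name in ("q_thr", "fq1_thr", "fq2_thr", "fq3_thr", "fq4_thr", "vicinity_ps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.search_window_ps
        if not lo < hi:
            raise ValueError("search window must be a non-empty interval")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["search_window_ps"] = list(self.search_window_ps)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Thresholds":
        d = dict(d)
        if "search_window_ps" in d:
            d["search_window_ps"] = tuple(d["search_window_ps"])
        return cls(**d)


@dataclass(frozen=True)
class QFeatures:
    """Time-domain features: main maximum (t0, a0) and flanking minima.

    ``a2`` is the minimum on the earlier side of the maximum, ``a1`` on
    the later side; q = a1/a2 with signed amplitudes (both minima of a
    physical echo are negative, so q > 0).
    """

    t0: float
    a0: float
    a1: float
    a2: float

    @property
    def q(self) -> float:
        return self.a1 / self.a2

    def to_dict(self) -> dict:
        return {"t0": self.t0, "a0": self.a0, "a1": self.a1, "a2": self.a2, "q": self.q}


@dataclass(frozen=True)
class FrequencyFeatures:
    """Reflectance feature points (max-normalised R) and their ratios.

    fa1/fa3: max/min of R over 0.18-0.5 THz; fa2, fa4, fa5: R at 0.3, 1.0
    and 1.5 THz.
    """

    fa1: float
    fa2: float
    fa3: float
    fa4: float
    fa5: float

    @property
    def fq1(self) -> float:
        return self.fa1 / self.fa2

    @property
    def fq2(self) -> float:
        return self.fa1 / self.fa3

    @property
    def fq3(self) -> float:
        return self.fa2 / self.fa3

    @property
    def fq4(self) -> float:
        return self.fa5 / self.fa4

    def to_dict(self) -> dict:
        return {"fa1": self.fa1, "fa2": self.fa2, "fa3": self.fa3, "fa4": self.fa4,
                "fa5": self.fa5, "fq1": self.fq1, "fq2": self.fq2, "fq3": self.fq3,
                "fq4": self.fq4}


@dataclass(frozen=True)
class DetectionResult:
    """Outcome of the two-criteria classifier for one trace."""

    label: str  # "genuine" | "spoof"
    fired: str  # "none" | "time_criterion" | "frequency_criterion"
    qfeat: QFeatures
    ffeat: FrequencyFeatures | None
    thresholds: Thresholds = field(default_factory=Thresholds, compare=False)

    def __post_init__(self):
        if (self.label == "spoof") != (self.fired != "none"):
            raise ValueError("label and fired criterion are inconsistent")

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "fired": self.fired,
            "q_features": self.qfeat.to_dict(),
            "frequency_features": self.ffeat.to_dict() if self.ffeat else None,
            "thresholds": self.thresholds.to_dict(),
        }


def q_coefficient(trace: TimeTrace, thresholds: Thresholds | None = None) -> QFeatures:
    """Extract the main maximum and flanking minima; q = a1/a2.

    The maximum is searched in the fixed window set by the window-surface
    position (9-11 ps by default); the minima in +-vicinity around it
    (ties broken towards earlier times by the scan order).  Non-negative
    minima or a vanishing a2 indicate a signal the q-test is not defined
    for and raise :class:`DegenerateSignalError`.
    """
    thr = thresholds or Thresholds()
    lo, hi = thr.search_window_ps
    t, a = trace.t, trace.amplitude
    if lo < t[0] or hi > t[-1]:
        raise ValueError("search window must lie inside the trace span")
    win = (t >= lo) & (t <= hi)
    if np.count_nonzero(win) < 3:
        raise ValueError("search window must contain at least 3 samples")
    k0 = np.flatnonzero(win)[int(np.argmax(a[win]))]
    t0, a0 = float(t[k0]), float(a[k0])
    before = (t > t0 - thr.vicinity_ps) & (t < t0)
    after = (t > t0) & (t < t0 + thr.vicinity_ps)
    if not np.any(before) or not np.any(after):
        raise ValueError("vicinity around the maximum is empty on one side")
    a2 = float(np.min(a[before]))
    a1 = float(np.min(a[after]))
    if a2 == 0.0:
        raise DegenerateSignalError("earlier-side minimum is exactly zero")
    if a1 >= 0.0 or a2 >= 0.0:
        raise DegenerateSignalError(
            "flanking minima are not both negative; q is undefined for this signal"
        )
    return QFeatures(t0=t0, a0=a0, a1=a1, a2=a2)


_FA_BAND = (0.18, 0.5)  # THz, search band for fa1/fa3
_FA_POINTS = (0.30, 1.0, 1.5)  # THz, point features fa2, fa4, fa5


def frequency_features(R: ReflectanceSpectrum) -> FrequencyFeatures:
    """Extract the five reflectance feature points and their ratios.

    R is max-normalised first (the fq ratios are normalisation
    invariant); point features are read by linear interpolation since the
    0.025 THz grid does not contain 0.30 THz exactly.
    """
    if R.nu[0] > _FA_BAND[0] or R.nu[-1] < _FA_POINTS[-1]:
        raise ValueError(
            f"spectrum must cover {_FA_BAND[0]}-{_FA_POINTS[-1]} THz for feature extraction"
        )
    peak = R.R.max()
    if peak <= 0:
        raise DegenerateSignalError("reflectance is identically zero")
    Rn = ReflectanceSpectrum(nu=R.nu, R=R.R / peak)
    sel = (Rn.nu >= _FA_BAND[0]) & (Rn.nu <= _FA_BAND[1])
    if not np.any(sel):
        raise ValueError("no bins inside the 0.18-0.5 THz feature band")
    fa1 = float(np.max(Rn.R[sel]))
    fa3 = float(np.min(Rn.R[sel]))
    fa2, fa4, fa5 = (Rn.at(nu) for nu in _FA_POINTS)
    if fa2 == 0.0 or fa3 == 0.0 or fa4 == 0.0:
        raise DegenerateSignalError("a feature-point amplitude is zero; ratios undefined")
    return FrequencyFeatures(fa1=fa1, fa2=fa2, fa3=fa3, fa4=fa4, fa5=fa5)


def classify(E1: TimeTrace, E0: TimeTrace,
             thresholds: Thresholds | None = None) -> DetectionResult:
    """Run the two-criteria algorithm on a sample/reference trace pair.

    q > q_thr flags a spoof outright (time criterion); otherwise the
    reflectance features are computed and the spoof flag requires all of
    fq1 > 4.5, fq2 > 3.5, fq3 < 1.21 and fq4 < 1.1 (frequency criterion).
    """
    thr = thresholds or Thresholds()
    qf = q_coefficient(E1, thr)
    if qf.q > thr.q_thr:
        return DetectionResult("spoof", "time_criterion", qf, None, thr)
    ff = frequency_features(reflectance(E1, E0))
    if (ff.fq1 > thr.fq1_thr and ff.fq2 > thr.fq2_thr
            and ff.fq3 < thr.fq3_thr and ff.fq4 < thr.fq4_thr):
        return DetectionResult("spoof", "frequency_criterion", qf, ff, thr)
    return DetectionResult("genuine", "none", qf, ff, thr)


# -- evaluation ----------------------------------------------------------

@dataclass(frozen=True)
class EvaluationReport:
    """Per-class and cumulative true/false detection rates (percent).

    TDR of a class is the fraction of its members classified correctly
    (spoof classes as spoof, the genuine class as genuine); FDR is the
    complement.  The cumulative row weights classes by sample count.
    """

    per_class: dict
    total_tdr: float
    total_fdr: float
    n_samples: int

    def to_dict(self) -> dict:
        return {"per_class": self.per_class, "total_tdr": self.total_tdr,
                "total_fdr": self.total_fdr, "n_samples": self.n_samples}

    def format_table(self) -> str:
        names = list(self.per_class) + ["total"]
        rows = {"TDR": [], "FDR": []}
        for c in self.per_class.values():
            rows["TDR"].append(c["tdr"])
            rows["FDR"].append(c["fdr"])
        rows["TDR"].append(self.total_tdr)
        rows["FDR"].append(self.total_fdr)
        width = max(len(n) for n in names + ["samples"]) + 2
        out = ["".ljust(8) + "".join(n.ljust(width) for n in names)]
        for key, vals in rows.items():
            out.append(key.ljust(8) + "".join(f"{v:.1f}%".ljust(width) for v in vals))
        counts = [str(c["n"]) for c in self.per_class.values()] + [str(self.n_samples)]
        out.append("n".ljust(8) + "".join(s.ljust(width) for s in counts))
        return "\n".join(out)


def evaluate(results: list[DetectionResult], truth: list[str],
             genuine_class: str = "genuine") -> EvaluationReport:
    """Score predictions against truth class labels.

    ``truth`` entries are class names (e.g. ``genuine``, ``group1``,
    ``group2``); every class other than ``genuine_class`` is a spoof
    class.  Rates are returned in percent, per class and cumulatively
    (count weighted).
    """
    if len(results) == 0:
        raise ValueError("nothing to evaluate")
    if len(results) != len(truth):
        raise ValueError("results and truth labels differ in length")
    per_class: dict[str, dict] = {}
    correct_total = 0
    for res, cls in zip(results, truth):
        expected = "genuine" if cls == genuine_class else "spoof"
        ok = res.label == expected
        rec = per_class.setdefault(cls, {"n": 0, "correct": 0})
        rec["n"] += 1
        rec["correct"] += ok
        correct_total += ok
    for rec in per_class.values():
        rec["tdr"] = 100.0 * rec["correct"] / rec["n"]
        rec["fdr"] = 100.0 - rec["tdr"]
    total_tdr = 100.0 * correct_total / len(results)
    return EvaluationReport(per_class=per_class, total_tdr=total_tdr,
                            total_fdr=100.0 - total_tdr, n_samples=len(results))
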