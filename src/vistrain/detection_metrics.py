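"""Confusion-matrix statistics for the blind-spot validation protocol.

Category semantics follow the validation study's (inverted) convention,
kept verbatim rather than normalised to the epidemiological one:

* TN — blind-spot stimulus, no click (correct non-reaction)
* FP — blind-spot stimulus, click (false reaction)
* FN — detectable stimulus, no click (false non-reaction)
* TP — detectable stimulus, click (correct reaction)

so sensitivity is the correct-rejection rate on blind-spot stimuli
(``tn / (tn + fp)``) and specificity the hit rate on detectable stimuli
(``tp / (tp + fn)``).  The random hit rate is marginal chance agreement:
with click fraction ``q = (tp + fp) / N``, ``rhr = q*D/N + (1-q)*B/N``
(B, D the blind-spot and detectable totals).  Undefined metrics (zero
denominators) are reported as NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "sen",
    "spe",
    "ppv",
    "npv",
    "hit_rate",
    "random_hit_rate",
    "ratz",
    "accuracy",
    "pool",
    "cohort_summary",
    "spearman_brown",
    "split_half_reliability",
    "reconstruct_matrix",
    "load_validation_cohort",
    "reproduce_report",
    "round_half_up",
]

METRIC_NAMES = ("sen", "spe", "ppv", "npv", "hr", "rhr", "ratz")


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts of one scored block (see module docstring for the convention)."""

    tn: int
    fp: int
    fn: int
    tp: int

    def __post_init__(self) -> None:
        if min(self.tn, self.fp, self.fn, self.tp) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion matrix must contain at least one trial")

    @property
    def n_blindspot(self) -> int:
        return self.tn + self.fp

    @property
    def n_detectable(self) -> int:
        return self.tp + self.fn

    @property
    def total(self) -> int:
        return self.tn + self.fp + self.fn + self.tp


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def sen(m: ConfusionMatrix) -> float:
    """Fraction of blind-spot stimuli correctly left unanswered."""
    return _ratio(m.tn, m.n_blindspot)


def spe(m: ConfusionMatrix) -> float:
    """Fraction of detectable stimuli correctly answered."""
    return _ratio(m.tp, m.n_detectable)


def ppv(m: ConfusionMatrix) -> float:
    """Correct blind-spot classifications among all non-reactions."""
    return _ratio(m.tn, m.tn + m.fn)


def npv(m: ConfusionMatrix) -> float:
    """Correct detectable classifications among all reactions."""
    return _ratio(m.tp, m.tp + m.fp)


def hit_rate(m: ConfusionMatrix) -> float:
    """Fraction of all scored trials classified correctly."""
    return (m.tn + m.tp) / m.total


def random_hit_rate(m: ConfusionMatrix) -> float:
    """Expected hit rate under chance given the click and category marginals."""
    n = m.total
    q = (m.tp + m.fp) / n
    return q * (m.n_detectable / n) + (1.0 - q) * (m.n_blindspot / n)


def ratz(m: ConfusionMatrix) -> float:
    """Chance-corrected hit rate: (hr - rhr) / (1 - rhr); NaN when rhr = 1."""
    r = random_hit_rate(m)
    if r >= 1.0:
        return math.nan
    return (hit_rate(m) - r) / (1.0 - r)


def accuracy(m: ConfusionMatrix) -> float:
    """(tp + tn) / N."""
    return (m.tp + m.tn) / m.total


def pool(matrices: Iterable[ConfusionMatrix]) -> ConfusionMatrix:
    """Element-wise sum of per-subject matrices."""
    ms = list(matrices)
    if not ms:
        raise ValueError("cannot pool an empty list of matrices")
    return ConfusionMatrix(
        tn=sum(m.tn for m in ms),
        fp=sum(m.fp for m in ms),
        fn=sum(m.fn for m in ms),
        tp=sum(m.tp for m in ms),
    )


@dataclass(frozen=True)
class MetricsReport:
    """The seven per-subject statistics plus accuracy."""

    sen: float
    spe: float
    ppv: float
    npv: float
    hr: float
    rhr: float
    ratz: float
    acc: float

    @classmethod
    def from_matrix(cls, m: ConfusionMatrix) -> "MetricsReport":
        return cls(
            sen=sen(m), spe=spe(m), ppv=ppv(m), npv=npv(m),
            hr=hit_rate(m), rhr=random_hit_rate(m), ratz=ratz(m), acc=accuracy(m),
        )

    def rounded(self, ndigits: int = 3) -> dict[str, float]:
        return {k: round_half_up(v, ndigits) for k, v in self.__dict__.items()}


def round_half_up(x: float, ndigits: int = 3) -> float:
    """Decimal half-up rounding, matching printed-table conventions."""
    x = float(x)
    if not math.isfinite(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def cohort_summary(matrices: Sequence[ConfusionMatrix]) -> pd.DataFrame:
    """Unweighted mean and sample SD of each metric across subjects."""
    if not matrices:
        raise ValueError("cohort_summary requires at least one matrix")
    rows = [MetricsReport.from_matrix(m) for m in matrices]
    df = pd.DataFrame([r.__dict__ for r in rows])
    out = pd.DataFrame({"mean": df.mean(), "sd": df.std(ddof=1)})
    if len(matrices) == 1:
        out["sd"] = 0.0
    return out


def spearman_brown(r: float) -> float:
    """Test-length-doubling prophecy: 2r / (1 + r); NaN at r = -1."""
    if r <= -1.0:
        return math.nan
    return 2.0 * r / (1.0 + r)


def split_half_reliability(records_per_subject: Sequence[Sequence]) -> tuple[float, float]:
    """Odd/even split-half reliability of blind-spot correct rejections.

    Scored trials are split by occurrence order within each category; per
    subject, the count of blind-spot correct rejections (no click) is taken
    per half.  Returns the Pearson correlation between halves across
    subjects and its Spearman-Brown correction; (NaN, NaN) when either half
    has zero variance.
    """
    if len(records_per_subject) < 3:
        raise ValueError("split-half reliability requires at least 3 subjects")
    halves = np.zeros((len(records_per_subject), 2))
    for s, records in enumerate(records_per_subject):
        scored_bs = [
            r for r in records if r.block == "scored" and r.category == "blindspot"
        ]
        for i, r in enumerate(scored_bs):
            if not r.clicked:
                halves[s, i % 2] += 1
    if halves[:, 0].std() == 0.0 or halves[:, 1].std() == 0.0:
        return (math.nan, math.nan)
    r = float(np.corrcoef(halves[:, 0], halves[:, 1])[0, 1])
    return (r, spearman_brown(r))


# ---------------------------------------------------------------------------
# Published-cohort reconstruction


def reconstruct_matrix(
    sen_value: float, spe_value: float, n_blindspot: int = 15, n_detectable: int = 85
) -> ConfusionMatrix:
    """Integer confusion matrix implied by printed sensitivity/specificity.

    ``tn = round(n_blindspot * sen)``, ``tp = round(n_detectable * spe)``
    (half-up), remainders fp/fn.
    """
    tn = int(math.floor(n_blindspot * sen_value + 0.5))
    tp = int(math.floor(n_detectable * spe_value + 0.5))
    return ConfusionMatrix(tn=tn, fp=n_blindspot - tn, fn=n_detectable - tp, tp=tp)


def load_validation_cohort(path=None) -> pd.DataFrame:
    """Load a published per-subject cohort table (columns subject, sen, spe;
    further printed metric columns are optional and used only for
    cross-checking).  Defaults to the bundled 40-subject fixture."""
    if path is None:
        with resources.files("vistrain.data").joinpath("validation_cohort.csv").open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(path)
    missing = {"subject", "sen", "spe"} - set(df.columns)
    if missing:
        raise ValueError(f"cohort table is missing columns: {sorted(missing)}")
    return df


def reproduce_report(cohort: pd.DataFrame | None = None) -> dict:
    """Recompute every per-subject metric from a published cohort table.

    Returns a dict with:

    * ``per_subject`` — DataFrame of reconstructed counts and all computed
      metrics (3-decimal half-up rounding),
    * ``summary`` — mean/SD per metric across subjects,
    * ``pooled`` — summed counts and pooled accuracy,
    * ``discrepancies`` — rows where a printed metric column (if present in
      the input) disagrees with the recomputed value after rounding.
    """
    if cohort is None:
        cohort = load_validation_cohort()
    matrices = [reconstruct_matrix(r.sen, r.spe) for r in cohort.itertuples()]
    reports = [MetricsReport.from_matrix(m) for m in matrices]

    per_subject = pd.DataFrame(
        {
            "subject": cohort["subject"].values,
            "tn": [m.tn for m in matrices],
            "fp": [m.fp for m in matrices],
            "fn": [m.fn for m in matrices],
            "tp": [m.tp for m in matrices],
            **{
                name: [round_half_up(getattr(r, name)) for r in reports]
                for name in METRIC_NAMES
            },
        }
    )

    discrepancies = []
    for name in METRIC_NAMES:
        col = f"printed_{name}" if f"printed_{name}" in cohort.columns else name
        if col not in cohort.columns or col in ("sen", "spe"):
            continue
        for subj, printed, computed in zip(
            cohort["subject"], cohort[col], per_subject[name]
        ):
            if not math.isclose(printed, computed, abs_tol=5e-4):
                discrepancies.append(
                    {"subject": subj, "metric": name, "printed": printed, "computed": computed}
                )

    pooled = pool(matrices)
    return {
        "per_subject": per_subject,
        "summary": cohort_summary(matrices),
        "pooled": {
            "tn": pooled.tn,
            "fp": pooled.fp,
            "fn": pooled.fn,
            "tp": pooled.tp,
            "accuracy": accuracy(pooled),
        },
        "discrepancies": pd.DataFrame(
            discrepancies, columns=["subject", "metric", "printed", "computed"]
        ),
    }
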