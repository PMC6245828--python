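"""Multi-expert rating analytics: groupings, Cohen kappa, consensus.

Ordinal tortuosity grades (0 none, 1 mild, 2 moderate, 3 severe) assigned by
several raters over one or more rating rounds are analysed with the standard
panel statistics: binary clinical groupings, pairwise chance-corrected
agreement (Cohen's kappa), per-image majority-vote consensus labels, and
consensus-percentage summaries.

The published marginal rating counts of a five-expert, 60-image fundus study
ship as packaged CSV fixtures (:func:`round1_grade_counts`,
:func:`binary_round_counts`, :func:`vote_counts`).  These are *marginals
only* -- the per-image expert labels behind them were never published, so
pairwise statistics cannot be recomputed from them; they anchor the grouping
arithmetic and serve as realistic scene-setting for simulations.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "GradeScale",
    "FOUR_GRADE_SCALE",
    "RatingTable",
    "BinaryGrouping",
    "TORTUOUS_GROUPING",
    "ASYMPTOMATIC_GROUPING",
    "MajorityLabels",
    "group_grades",
    "group_marginal_counts",
    "cohen_kappa",
    "kappa_is_defined",
    "kappa_matrix",
    "majority_vote",
    "consensus_summary",
    "interpret_kappa",
    "round1_grade_counts",
    "binary_round_counts",
    "vote_counts",
]


@dataclass(frozen=True)
class GradeScale:
    """Ordered ordinal grade labels, coded as contiguous integers from 0."""

    levels: tuple

    def __len__(self) -> int:
        return len(self.levels)


FOUR_GRADE_SCALE = GradeScale(("none", "mild", "moderate", "severe"))
BINARY_SCALE = GradeScale(("asymptomatic", "symptomatic"))


@dataclass(frozen=True)
class RatingTable:
    """Image-by-rater grade matrix for one rating round.

    ``grades`` is a DataFrame indexed by image id with one integer column per
    rater; every cell must be a valid grade in ``range(n_levels)``.
    """

    grades: pd.DataFrame
    round: str
    n_levels: int = 4

    def __post_init__(self) -> None:
        df = self.grades
        if df.index.has_duplicates or df.columns.has_duplicates:
            raise ValueError("image and rater identifiers must be unique")
        vals = df.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            raise ValueError("grades must be integers")
        if vals.size and (vals.min() < 0 or vals.max() >= self.n_levels):
            raise ValueError("grade outside the scale")

    @property
    def raters(self) -> list:
        return list(self.grades.columns)

    @property
    def images(self) -> list:
        return list(self.grades.index)


@dataclass(frozen=True)
class BinaryGrouping:
    """Partition of an ordinal grade scale into two clinical classes."""

    name: str
    class0: frozenset
    class1: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(self, "class0", frozenset(self.class0))
        object.__setattr__(self, "class1", frozenset(self.class1))
        if not self.class0 or not self.class1 or (self.class0 & self.class1):
            raise ValueError("classes must be non-empty and disjoint")

    def grades(self) -> frozenset:
        return self.class0 | self.class1

    def map_grade(self, g: int) -> int:
        if g in self.class0:
            return 0
        if g in self.class1:
            return 1
        raise ValueError(f"grade {g} outside the grouping")


#: no sign of tortuosity vs any tortuosity level
TORTUOUS_GROUPING = BinaryGrouping("tortuous_vs_non", frozenset({0}), frozenset({1, 2, 3}))
#: none/mild (no treatment need) vs moderate/severe (clinically symptomatic)
ASYMPTOMATIC_GROUPING = BinaryGrouping(
    "asymptomatic_vs_symptomatic", frozenset({0, 1}), frozenset({2, 3})
)

GROUPINGS = {
    "tortuous": TORTUOUS_GROUPING,
    "asymptomatic": ASYMPTOMATIC_GROUPING,
}


def group_grades(table: RatingTable, grouping: BinaryGrouping) -> RatingTable:
    """Map a four-grade table cell-wise into a binary table."""
    if table.n_levels == 2:
        raise ValueError("table is already binary")
    missing = set(np.unique(table.grades.to_numpy())) - set(grouping.grades())
    if missing:
        raise ValueError(f"grades {sorted(missing)} not covered by the grouping")
    mapped = table.grades.map(grouping.map_grade)
    return RatingTable(grades=mapped.astype(int), round=table.round, n_levels=2)


def group_marginal_counts(counts: pd.DataFrame, grouping: BinaryGrouping) -> pd.DataFrame:
    """Collapse per-grade marginal counts (rows indexed by grade code) into
    the two classes of ``grouping``; column sums are conserved."""
    rows = []
    for cls, members in ((0, grouping.class0), (1, grouping.class1)):
        members = [g for g in sorted(members) if g in counts.index]
        rows.append(counts.loc[members].sum(axis=0).rename(cls))
    out = pd.DataFrame(rows)
    out.index.name = "class"
    return out


# ---------------------------------------------------------------------------
# Cohen kappa


def cohen_kappa(a, b) -> float:
    """Chance-corrected agreement ``(p_o - p_e) / (1 - p_e)``.

    ``p_e`` comes from the product of the two raters' marginal label
    distributions.  Returns NaN (the *undefined* flag) when both raters are
    constant and identical, where chance agreement saturates at 1.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("rating vectors must be 1-D and equally long")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 rated items")
    labels = np.union1d(a, b)
    la = np.searchsorted(labels, a)
    lb = np.searchsorted(labels, b)
    L = labels.size
    conf = np.zeros((L, L))
    np.add.at(conf, (la, lb), 1.0)
    po = np.trace(conf) / n
    pe = float(conf.sum(axis=1) @ conf.sum(axis=0)) / (n * n)
    if 1.0 - pe < 1e-12:
        return float("nan")
    return float((po - pe) / (1.0 - pe))


def kappa_is_defined(value: float) -> bool:
    return not np.isnan(value)


def _rating_vectors(tables, consensus=None, tie_rule="higher") -> pd.DataFrame:
    """Columns for every rater/round plus majority-vote and consensus vectors."""
    images = tables[0].images
    for t in tables[1:]:
        if t.images != images:
            raise ValueError("tables must share the same image set and order")
    cols = {}
    for t in tables:
        for r in t.raters:
            cols[f"{r}_{t.round}"] = t.grades[r].to_numpy()
    for t in tables:
        cols[f"V_{t.round}"] = majority_vote([t], tie_rule=tie_rule).labels.to_numpy()
    if len(tables) > 1:
        pooled_name = "V_" + "".join(t.round for t in tables)
        cols[pooled_name] = majority_vote(tables, tie_rule=tie_rule).labels.to_numpy()
    if consensus is not None:
        cons = pd.Series(consensus)
        cols["Rc"] = cons.loc[images].to_numpy()
    return pd.DataFrame(cols, index=images)


def kappa_matrix(tables, consensus=None, tie_rule: str = "higher") -> pd.DataFrame:
    """Symmetric matrix of pairwise Cohen kappas.

    Columns cover every rater in every round, the per-round majority vote
    ``V_<round>``, the pooled-round majority vote, and an optional consensus
    vector ``Rc``.  Undefined pairs are NaN.
    """
    vecs = _rating_vectors(tables, consensus=consensus, tie_rule=tie_rule)
    names = list(vecs.columns)
    out = pd.DataFrame(np.nan, index=names, columns=names)
    for i, ni in enumerate(names):
        for nj in names[i:]:
            k = cohen_kappa(vecs[ni].to_numpy(), vecs[nj].to_numpy())
            out.loc[ni, nj] = k
            out.loc[nj, ni] = k
    return out


# ---------------------------------------------------------------------------
# majority voting and consensus summaries


@dataclass(frozen=True)
class MajorityLabels:
    """Per-image most-voted label with tie flags."""

    labels: pd.Series
    ties: pd.Series
    source: str


def majority_vote(tables, tie_rule: str = "higher") -> MajorityLabels:
    """Most-voted label per image over the pooled votes of ``tables``.

    Votes from all raters of all given rounds are pooled (an expert voting in
    two rounds contributes two votes).  Exact ties are resolved by
    ``tie_rule`` -- ``"higher"`` (default; the clinically conservative, more
    symptomatic grade wins) or ``"lower"`` -- and flagged.
    """
    if not tables:
        raise ValueError("need at least one rating table")
    if tie_rule not in ("higher", "lower"):
        raise ValueError("tie_rule must be 'higher' or 'lower'")
    images = tables[0].images
    votes = np.hstack([t.grades.loc[images].to_numpy() for t in tables])
    n_levels = max(t.n_levels for t in tables)
    counts = np.stack(
        [(votes == g).sum(axis=1) for g in range(n_levels)], axis=1
    )
    best = counts.max(axis=1)
    is_best = counts == best[:, None]
    ties = is_best.sum(axis=1) > 1
    if tie_rule == "higher":
        labels = n_levels - 1 - np.argmax(is_best[:, ::-1], axis=1)
    else:
        labels = np.argmax(is_best, axis=1)
    source = "V_" + "".join(t.round for t in tables)
    return MajorityLabels(
        labels=pd.Series(labels.astype(int), index=images, name=source),
        ties=pd.Series(ties, index=images, name="tie"),
        source=source,
    )


def consensus_summary(table: RatingTable) -> dict:
    """Percentages of images whose modal label reaches R, R-1 and R-2 votes.

    For the canonical five-rater panel these are the full-consensus, the
    four-coincidence and the at-least-three-coincidence percentages.  The
    returned dict maps the vote threshold to a percentage; values are
    monotone non-increasing in the threshold.
    """
    R = len(table.raters)
    votes = table.grades.to_numpy()
    counts = np.stack(
        [(votes == g).sum(axis=1) for g in range(table.n_levels)], axis=1
    )
    modal = counts.max(axis=1)
    out = {}
    for thr in (R, R - 1, R - 2):
        out[thr] = float(100.0 * np.mean(modal >= thr))
    return out


_KAPPA_BANDS = (
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.00, "almost perfect"),
)


def interpret_kappa(value: float) -> str:
    """Standard qualitative band for a kappa value.

    Bands are the half-open intervals [0, 0.20], (0.20, 0.40], (0.40, 0.60],
    (0.60, 0.80], (0.80, 1]; negative values are 'less than chance'.
    """
    if np.isnan(value) or value < -1.0 or value > 1.0:
        raise ValueError("kappa must lie in [-1, 1]")
    if value < 0.0:
        return "less than chance"
    for upper, label in _KAPPA_BANDS:
        if value <= upper:
            return label
    return "almost perfect"


# ---------------------------------------------------------------------------
# packaged marginal-count fixtures


def _load_csv(name: str) -> pd.DataFrame:
    with resources.files("retinotort.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def round1_grade_counts() -> pd.DataFrame:
    """Four-grade marginal counts per expert for the first blind round.

    Rows indexed by grade code 0..3; columns E1..E5.  Marginals only -- no
    per-image labels exist in public form.
    """
    df = _load_csv("round1_grade_counts.csv")
    return df.set_index("grade")[["E1", "E2", "E3", "E4", "E5"]]


def binary_round_counts() -> pd.DataFrame:
    """Asymptomatic/symptomatic marginal counts per expert and round.

    MultiIndex (round, class code); columns E1..E5.  Round R1 is the grouped
    four-grade round, round R2 a native binary rating round.
    """
    df = _load_csv("binary_round_counts.csv")
    return df.set_index(["round", "class"])[["E1", "E2", "E3", "E4", "E5"]]


def vote_counts() -> pd.DataFrame:
    """Binary marginal counts of the majority-vote and consensus reference
    label sets (V_R1, V_R2, pooled V_R1R2 and the consensus session Rc)."""
    df = _load_csv("vote_counts.csv")
    return df.set_index("class")[["V_R1", "V_R2", "V_R1R2", "Rc"]]
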