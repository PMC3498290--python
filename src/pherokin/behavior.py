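"""Wind-tunnel behavioral statistics and EAG response summaries.

Behavioral responses are scored as an ordered sequence of steps (taking
flight → halfway → close approach → source contact), each conditional on the
previous one, so counts are non-increasing along the sequence within a
treatment.  Treatments are compared per step with a Pearson χ² homogeneity
test on the responders/non-responders table and summarized as a compact
letter display (treatments share a letter iff not significantly different).

EAG depolarizations are normalized per antenna to the standard-stimulus
response recorded in the same session (normalized % = 100·raw/standard),
averaged over replicates within antenna and then across antennae; the antenna
is the statistical unit for the unpaired two-sided Student t comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DomainError, NormalizationError

__all__ = [
    "BEHAVIOR_STEPS",
    "BehaviorTable",
    "Chi2Result",
    "EAGRecordSet",
    "EAGSummary",
    "proportions",
    "chi2_homogeneity",
    "normalize_eag",
]

BEHAVIOR_STEPS = ("taking_flight", "halfway", "close_approach", "source_contact")
MAX_REPLICATES_PER_ANTENNA = 4


@dataclass
class BehaviorTable:
    """Responder counts per treatment × ordered behavior step."""

    treatments: list[str]
    behaviors: list[str]
    counts: np.ndarray  # shape (n_treatments, n_behaviors)
    n: np.ndarray  # insects per treatment

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        self.n = np.asarray(self.n, dtype=int)
        if self.counts.shape != (len(self.treatments), len(self.behaviors)):
            raise DomainError("counts must be (treatments × behaviors)")
        if np.any(self.n <= 0):
            raise DomainError("N must be positive for every treatment")
        if np.any(self.counts < 0) or np.any(self.counts > self.n[:, None]):
            raise DomainError("counts must satisfy 0 <= count <= N")
        if np.any(np.diff(self.counts, axis=1) > 0):
            raise DomainError(
                "counts must be non-increasing along the behavior sequence "
                "(each step requires the previous one)"
            )

    @classmethod
    def from_csv(cls, path) -> "BehaviorTable":
        """Read the ``treatment, behavior, count, n`` schema (order preserved)."""
        df = pd.read_csv(path)
        treatments = list(dict.fromkeys(df["treatment"]))
        behaviors = list(dict.fromkeys(df["behavior"]))
        counts = np.zeros((len(treatments), len(behaviors)), dtype=int)
        n = np.zeros(len(treatments), dtype=int)
        for _, row in df.iterrows():
            i = treatments.index(row["treatment"])
            j = behaviors.index(row["behavior"])
            counts[i, j] = row["count"]
            n[i] = row["n"]
        return cls(treatments, behaviors, counts, n)

    def to_csv(self, path) -> None:
        rows = [
            (t, b, int(self.counts[i, j]), int(self.n[i]))
            for i, t in enumerate(self.treatments)
            for j, b in enumerate(self.behaviors)
        ]
        pd.DataFrame(rows, columns=["treatment", "behavior", "count", "n"]).to_csv(
            path, index=False
        )


@dataclass
class Chi2Result:
    statistic: float
    df: int
    pvalue: float
    expected: np.ndarray
    low_expected: bool
    pairwise_p: pd.DataFrame
    letters: dict[str, str]
    alpha: float


@dataclass
class EAGSummary:
    antenna_means: pd.DataFrame  # antenna × treatment normalized %
    mean_normalized_pct: dict[str, float]
    corrected_pct: float
    t_statistic: float
    p_value: float
    n_rejected: int = 0


def _clopper_pearson(count: int, n: int, alpha: float) -> tuple[float, float]:
    # boundary counts use the one-sided (rule-of-three-type) bound
    if count == 0:
        return 0.0, 1.0 - alpha ** (1.0 / n)
    if count == n:
        return alpha ** (1.0 / n), 1.0
    lower = stats.beta.ppf(alpha / 2.0, count, n - count + 1)
    upper = stats.beta.isf(alpha / 2.0, count + 1, n - count)
    return float(lower), float(upper)


def proportions(table: BehaviorTable, alpha: float = 0.05) -> pd.DataFrame:
    """Per-cell response proportions with exact Clopper–Pearson intervals."""
    rows = []
    for i, t in enumerate(table.treatments):
        for j, b in enumerate(table.behaviors):
            c, n = int(table.counts[i, j]), int(table.n[i])
            lo, hi = _clopper_pearson(c, n, alpha)
            rows.append((t, b, c, n, c / n, lo, hi))
    return pd.DataFrame(
        rows,
        columns=["treatment", "behavior", "count", "n", "proportion", "ci_low", "ci_high"],
    )


def _chi2_2col(observed: np.ndarray, correction: bool) -> tuple[float, int, float]:
    """Pearson χ² on an R×2 responded/not table; degenerate columns give p = 1."""
    col_totals = observed.sum(axis=0)
    df = observed.shape[0] - 1
    if np.any(col_totals == 0):
        # all treatments at the same extreme: trivially homogeneous
        return 0.0, df, 1.0
    stat, p, df, _ = stats.chi2_contingency(observed, correction=correction)
    return float(stat), int(df), float(p)


def chi2_homogeneity(
    table: BehaviorTable,
    behavior: str,
    alpha: float = 0.05,
    *,
    correction: bool = False,
    holm: bool = False,
) -> Chi2Result:
    """χ² homogeneity of one behavior step across treatments, with letters.

    The overall Pearson statistic is computed on the treatments × 2
    (responded / not responded) table; pairwise 2×2 tests at ``alpha``
    (Yates continuity correction off by default, Holm adjustment optional)
    define a non-significance graph whose maximal cliques become the compact
    letter display.
    """
    if behavior not in table.behaviors:
        raise DomainError(f"unknown behavior {behavior!r}; table has {table.behaviors}")
    j = table.behaviors.index(behavior)
    responded = table.counts[:, j]
    observed = np.column_stack([responded, table.n - responded])
    if observed.sum() == 0:
        raise DomainError("degenerate table: no observations")
    if len(table.treatments) < 2:
        raise DomainError("chi2_homogeneity requires at least 2 treatments")

    stat, df, pvalue = _chi2_2col(observed, correction)
    row_tot = observed.sum(axis=1, keepdims=True)
    col_tot = observed.sum(axis=0, keepdims=True)
    expected = row_tot * col_tot / observed.sum()
    low_expected = bool(np.any(expected < 5))
    if low_expected:
        warnings.warn(
            f"chi2_homogeneity({behavior!r}): expected count(s) below 5; "
            "asymptotic p-values may be unreliable",
            stacklevel=2,
        )

    t_names = table.treatments
    pairs = [(a, b) for i, a in enumerate(t_names) for b in t_names[i + 1 :]]
    raw_p = []
    for a, b in pairs:
        ia, ib = t_names.index(a), t_names.index(b)
        _, _, p = _chi2_2col(observed[[ia, ib]], correction)
        raw_p.append(p)
    if holm and pairs:
        raw_p = list(multipletests(raw_p, alpha=alpha, method="holm")[1])
    pmat = pd.DataFrame(1.0, index=t_names, columns=t_names)
    for (a, b), p in zip(pairs, raw_p):
        pmat.loc[a, b] = pmat.loc[b, a] = p

    letters = _letter_display(t_names, pmat, alpha)
    return Chi2Result(
        statistic=stat,
        df=df,
        pvalue=pvalue,
        expected=expected,
        low_expected=low_expected,
        pairwise_p=pmat,
        letters=letters,
        alpha=alpha,
    )


def _letter_display(names: list[str], pmat: pd.DataFrame, alpha: float) -> dict[str, str]:
    """Compact letter display from the non-significance graph's maximal cliques."""
    g = nx.Graph()
    g.add_nodes_from(names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if pmat.loc[a, b] > alpha:
                g.add_edge(a, b)
    cliques = sorted(
        nx.find_cliques(g), key=lambda c: (min(names.index(m) for m in c), sorted(c))
    )
    letters: dict[str, list[str]] = {t: [] for t in names}
    for k, clique in enumerate(cliques):
        symbol = chr(ord("a") + k)
        for member in clique:
            letters[member].append(symbol)
    return {t: "".join(sorted(ls)) for t, ls in letters.items()}


@dataclass
class EAGRecordSet:
    """Per-stimulation EAG records; rows (antenna, replicate, treatment, mV)."""

    df: pd.DataFrame = field(repr=False)

    REQUIRED = ("antenna", "replicate", "treatment", "raw_mv", "standard_mv")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise DomainError(f"EAGRecordSet missing columns: {missing}")
        reps = self.df.groupby(["antenna", "treatment"]).size()
        if (reps > MAX_REPLICATES_PER_ANTENNA).any():
            raise DomainError(
                f"more than {MAX_REPLICATES_PER_ANTENNA} replicates on one antenna"
            )

    @classmethod
    def from_csv(cls, path) -> "EAGRecordSet":
        """Read ``antenna, replicate, treatment, raw_mv, standard_mv[, blank_mv]``.

        When a ``blank_mv`` column is present, its values are expanded into
        additional rows with treatment ``"blank"`` sharing the same antenna,
        replicate and standard.
        """
        df = pd.read_csv(path)
        if "blank_mv" in df.columns:
            blanks = df[["antenna", "replicate", "standard_mv", "blank_mv"]].copy()
            blanks = blanks.rename(columns={"blank_mv": "raw_mv"})
            blanks["treatment"] = "blank"
            df = pd.concat(
                [df.drop(columns=["blank_mv"]), blanks], ignore_index=True
            )
        return cls(df[list(cls.REQUIRED)])


def normalize_eag(
    records: EAGRecordSet,
    treatment: str = "pheromone",
    blank: str = "blank",
) -> EAGSummary:
    """Normalize to the same-antenna standard and compare treatment vs blank.

    normalized % = 100·raw/standard, averaged over replicates within antenna
    and then across antennae; corrected % = mean(treatment) − mean(blank).
    The t statistic is the unpaired two-sided Student t on antenna-level
    means.  Records without a positive standard are rejected with a warning.
    """
    df = records.df.copy()
    good = df["standard_mv"] > 0
    n_rejected = int((~good).sum())
    if n_rejected:
        warnings.warn(
            f"normalize_eag: rejected {n_rejected} record(s) with missing or "
            "non-positive standard response",
            stacklevel=2,
        )
    df = df[good]
    for name in (treatment, blank):
        if name not in set(df["treatment"]):
            raise NormalizationError(f"no usable records for treatment {name!r}")
    df["normalized_pct"] = 100.0 * df["raw_mv"] / df["standard_mv"]
    antenna_means = (
        df.groupby(["antenna", "treatment"])["normalized_pct"].mean().unstack("treatment")
    )
    means = {t: float(antenna_means[t].mean()) for t in antenna_means.columns}
    a = antenna_means[treatment].dropna()
    b = antenna_means[blank].dropna()
    t_stat, p_val = stats.ttest_ind(a, b)
    return EAGSummary(
        antenna_means=antenna_means,
        mean_normalized_pct=means,
        corrected_pct=means[treatment] - means[blank],
        t_statistic=float(t_stat),
        p_value=float(p_val),
        n_rejected=n_rejected,
    )
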