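"""Respondent data: printed marginals, count reconstruction, synthetic matrices.

The study published only marginal percentages of emotion (and action)
selection per scenario and group — no per-participant data.  Because the
group sizes are small (n = 13 TBI, n = 11 control in the actor test) each
percentage determines a unique integer selection count k via
k = round(pct * n / 100); for the audience test the per-scenario group
sizes are unprinted and are inferred as the smallest n that makes every
printed percentage consistent.

``generate_respondents`` builds synthetic per-participant binary
selection matrices that stand in for the unpublished raw data: in
``exact_marginal`` mode every column sum equals the reconstructed count
(so any statistic linear in the column sums is reproduced exactly, for
every seed); ``bernoulli`` mode draws i.i.d. selections with p = k/n.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

#: The 12-emotion answer set, in the printed row order of the actor
#: emotion-choice table (the canonical column order of all matrices).
EMOTIONS: tuple[str, ...] = (
    "distress", "joy", "fear", "hope", "pride", "shame",
    "admiration", "reproach", "gratification", "gratitude",
    "remorse", "anger",
)

#: Group sizes in the actor test.
ACTOR_GROUP_SIZES = {"TBI": 13, "control": 11}

#: Residual tolerance for pct <-> k consistency.  Strict one-decimal
#: rounding gives residuals <= 0.05; the extra margin absorbs the
#: source's occasionally inconsistent rounding.
RESIDUAL_TOL = 0.06


class MarginalInconsistencyError(ValueError):
    """A printed percentage is not consistent with any integer count."""


def _data_path(name: str) -> Path:
    return Path(importlib.resources.files("moralagent")) / "data" / name


def load_emotion_marginals() -> pd.DataFrame:
    """The packaged emotion-choice marginal table (long format).

    One row per table x scenario x role x group x emotion, with the
    percentage, the model-prediction mark, a provisional flag (set for
    the garbled other-character table) and the printed cell text.
    """
    df = pd.read_csv(_data_path("emotion_marginals.csv"))
    df["pct"] = df["pct"].astype(float)
    return df


def load_action_marginals() -> pd.DataFrame:
    """The packaged action-choice marginal table for the actor scenarios."""
    df = pd.read_csv(_data_path("action_marginals.csv"))
    df["pct"] = df["pct"].astype(float)
    return df


def pct_to_count(pct: float, n: int) -> int:
    """Recover the integer selection count behind a printed percentage.

    k = round(pct * n / 100); the reconstruction must round-trip to the
    printed one-decimal percentage within ``RESIDUAL_TOL``, otherwise the
    cell is flagged as inconsistent.  For n <= 13 the count is unique at
    one-decimal resolution.
    """
    if not 0.0 <= pct <= 100.0:
        raise ValueError(f"percentage outside [0, 100]: {pct}")
    if not 1 <= n <= 30:
        raise ValueError(f"group size outside [1, 30]: {n}")
    k = int(round(pct * n / 100.0))
    residual = abs(100.0 * k / n - pct)
    if residual > RESIDUAL_TOL:
        raise MarginalInconsistencyError(
            f"pct={pct} is inconsistent with n={n}: nearest count k={k} "
            f"gives {100.0 * k / n:.1f} (residual {residual:.2f})")
    return k


def infer_group_size(pcts: list[float], n_max: int = 30) -> int:
    """Smallest n <= n_max consistent with every non-zero percentage."""
    pcts = [p for p in pcts if p > 0]
    if not pcts:
        raise ValueError("need at least one non-zero percentage")
    for n in range(1, n_max + 1):
        try:
            for p in pcts:
                pct_to_count(p, n)
        except (MarginalInconsistencyError, ValueError):
            continue
        return n
    raise MarginalInconsistencyError(
        f"no group size <= {n_max} is consistent with {pcts}")


@dataclass
class MarginalTable:
    """Reconstructed per-emotion selection counts for one scenario x group."""

    scenario: str
    role: str
    group: str
    n: int
    counts: dict[str, int]          # emotion -> k, all 12 emotions
    predicted: frozenset[str]
    provisional: bool = False

    @property
    def count_vector(self) -> np.ndarray:
        return np.array([self.counts[e] for e in EMOTIONS], dtype=int)


def reconstruct_counts(df: pd.DataFrame | None = None) -> list[MarginalTable]:
    """Reconstruct integer counts for every packaged scenario x role x group.

    Actor group sizes are fixed (13 / 11); audience group sizes are
    inferred per scenario and group from the main-character percentages.
    """
    df = load_emotion_marginals() if df is None else df
    tables: list[MarginalTable] = []
    for (scenario, role, group), block in df.groupby(
            ["scenario", "role", "group"], sort=False):
        if role == "protagonist":
            n = ACTOR_GROUP_SIZES[group]
        else:
            main = df[(df.scenario == scenario) & (df.role == "main")
                      & (df.group == group)]
            n = infer_group_size(list(main.pct))
        counts = {row.emotion: pct_to_count(row.pct, n)
                  for row in block.itertuples()}
        tables.append(MarginalTable(
            scenario=scenario, role=role, group=group, n=n, counts=counts,
            predicted=frozenset(block[block.predicted == 1].emotion),
            provisional=bool(block.provisional.any())))
    return tables


def get_marginal_table(tables: list[MarginalTable], scenario: str,
                       group: str, role: str = "protagonist") -> MarginalTable:
    for t in tables:
        if (t.scenario, t.group, t.role) == (scenario, group, role):
            return t
    raise KeyError(f"no marginal table for {scenario}/{role}/{group}")


@dataclass
class SelectionMatrix:
    """n participants x 12 emotions binary selections for one scenario."""

    scenario: str
    group: str
    matrix: np.ndarray              # shape (n, 12), entries in {0, 1}
    mode: str                       # "exact_marginal" | "bernoulli"
    seed: int

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if m.ndim != 2 or m.shape[1] != len(EMOTIONS):
            raise ValueError(f"matrix must be n x {len(EMOTIONS)}")
        if not np.isin(m, (0, 1)).all():
            raise ValueError("matrix entries must be binary")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def column_sums(self) -> np.ndarray:
        return self.matrix.sum(axis=0)

    def selected_sets(self) -> list[frozenset[str]]:
        return [frozenset(e for e, v in zip(EMOTIONS, row) if v)
                for row in self.matrix]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=list(EMOTIONS))

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def generate_respondents(marginals: MarginalTable,
                         mode: str = "exact_marginal",
                         seed: int = 0) -> SelectionMatrix:
    """Synthesize a per-participant selection matrix from marginal counts.

    exact_marginal: for each emotion, exactly k ones placed on a seeded
    random permutation of the participants, so column sums are exact and
    seed-independent.  bernoulli: i.i.d. draws with p = k/n per emotion.
    """
    rng = np.random.default_rng(seed)
    n = marginals.n
    k = marginals.count_vector
    if (k > n).any():
        raise ValueError("count exceeds group size")
    if mode == "exact_marginal":
        m = np.zeros((n, len(EMOTIONS)), dtype=int)
        for j, kj in enumerate(k):
            rows = rng.permutation(n)[:kj]
            m[rows, j] = 1
    elif mode == "bernoulli":
        p = k / n
        m = (rng.random((n, len(EMOTIONS))) < p).astype(int)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return SelectionMatrix(scenario=marginals.scenario, group=marginals.group,
                           matrix=m, mode=mode, seed=seed)


def reconstruct_action_counts() -> pd.DataFrame:
    """Integer action-choice counts for the actor scenarios.

    The control column of the printed action table is internally
    inconsistent with the printed control action-score mean (2.00 printed
    vs 1.82 reconstructed); the counts returned here are the faithful
    reconstruction, and the discrepancy is surfaced by the reporting
    layer, not resolved.
    """
    df = load_action_marginals().copy()
    df["n"] = df.group.map(ACTOR_GROUP_SIZES)
    df["count"] = [pct_to_count(p, n) for p, n in zip(df.pct, df.n)]
    return df


def generate_action_choices(scenario: str, group: str, seed: int = 0,
                            counts: pd.DataFrame | None = None) -> list[str]:
    """Per-participant action choices with exact marginal counts (seeded)."""
    df = reconstruct_action_counts() if counts is None else counts
    block = df[(df.scenario == scenario) & (df.group == group)]
    n = ACTOR_GROUP_SIZES[group]
    choices = [p for p, k in zip(block["plan"], block["count"])
               for _ in range(int(k))]
    if len(choices) != n:
        raise MarginalInconsistencyError(
            f"{scenario}/{group}: action counts sum to {len(choices)}, "
            f"expected {n}")
    rng = np.random.default_rng(seed)
    return [choices[i] for i in rng.permutation(n)]
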