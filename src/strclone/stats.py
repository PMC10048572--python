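"""2x2 contingency statistics and growth-rank stratification.

The association measure throughout is the odds ratio OR = ad/bc with the
Woolf (log-normal) 95% confidence interval

    exp( ln OR ± 1.96 * sqrt(1/a + 1/b + 1/c + 1/d) ).

Significance comes from the two-tailed Fisher exact test (point-probability
convention: sum the hypergeometric probabilities of every table with the
same margins whose probability does not exceed that of the observed table)
and from the Pearson chi-square for 2x2 tables *without* continuity
correction,

    chi2 = n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)),  df = 1.

The uncorrected chi-square is deliberate: it is the dialect that reproduces
the published p-values this package is validated against; a Yates-corrected
variant is available behind an explicit flag.

Growth-rank stratification: clones picked later grew slower, so the serial
number is a growth-rate proxy. Cohorts are cut into contiguous equal blocks
by serial rank, adjacent fast blocks are merged while they are statistically
indistinguishable, and the slowest block is compared against the merged
"normal" group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.special import gammaln
from scipy.stats import beta as beta_dist
from scipy.stats import chi2 as chi2_dist

from .caller import ClonalStatus
from .errors import ValidationError, ZeroCellError

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class Table2x2:
    """Counts (a, b) in group 1 and (c, d) in group 2; a/c are the events."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise ValidationError(f"2x2 cells must be non-negative integers: {cells}")
        if self.a + self.b < 1 or self.c + self.d < 1:
            raise ValidationError("each group of a 2x2 table needs at least one count")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)

    def transpose_groups(self) -> "Table2x2":
        """Swap the two groups (rows)."""
        return Table2x2(self.c, self.d, self.a, self.b)

    def swap_outcome(self) -> "Table2x2":
        """Swap event and non-event columns."""
        return Table2x2(self.b, self.a, self.d, self.c)

    def expected(self) -> np.ndarray:
        r = np.array([self.a + self.b, self.c + self.d], dtype=float)
        c = np.array([self.a + self.c, self.b + self.d], dtype=float)
        return np.outer(r, c) / self.n


@dataclass(frozen=True)
class ContingencyResult:
    """Full analysis record for one 2x2 comparison."""

    table: Table2x2
    or_: float
    ci_low: float
    ci_high: float
    p_fisher: float
    chi2: Optional[float]
    p_chi2: Optional[float]
    method_note: str

    @property
    def p_surfaced(self) -> float:
        if self.method_note == "fisher" or self.p_chi2 is None:
            return self.p_fisher
        return self.p_chi2


# ---------------------------------------------------------------------------
# Core statistics
# ---------------------------------------------------------------------------

def odds_ratio_woolf(
    t: Table2x2, *, haldane: bool = False
) -> tuple[float, float, float]:
    """Odds ratio with Woolf 95% CI; ``(or, ci_low, ci_high)``.

    A zero cell makes the OR or its variance degenerate; by default this
    raises :class:`ZeroCellError`. Passing ``haldane=True`` applies the
    Haldane–Anscombe +0.5 correction to every cell — explicitly, never
    silently.
    """
    a, b, c, d = (float(x) for x in t.cells)
    if haldane:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    elif 0 in t.cells:
        raise ZeroCellError(
            f"zero cell in {t.cells}; pass haldane=True for the +0.5 correction"
        )
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    half = Z_95 * se
    log_or = math.log(or_)
    return or_, math.exp(log_or - half), math.exp(log_or + half)


def fisher_exact_two_tailed(t: Table2x2) -> float:
    """Two-tailed Fisher exact p, point-probability convention.

    Enumerates the full hypergeometric family of the observed margins in
    log space (gammaln), so tables with totals up to ~1e4 are exact and
    overflow-safe. Tables whose point probability exceeds the observed one
    by at most a 1e-7 relative tolerance are included, matching the usual
    software convention for ties.
    """
    n = t.n
    r = t.a + t.b
    c1 = t.a + t.c
    kmin = max(0, r + c1 - n)
    kmax = min(r, c1)
    ks = np.arange(kmin, kmax + 1)
    logp = (
        gammaln(r + 1) - gammaln(ks + 1) - gammaln(r - ks + 1)
        + gammaln(n - r + 1) - gammaln(c1 - ks + 1) - gammaln(n - r - c1 + ks + 1)
        - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
    )
    lp_obs = logp[t.a - kmin]
    include = logp <= lp_obs + math.log1p(1e-7)
    from scipy.special import logsumexp

    p = float(np.exp(logsumexp(logp[include])))
    return min(p, 1.0)


def pearson_chi2_2x2(
    t: Table2x2, *, correction: bool = False
) -> tuple[float, float]:
    """Pearson chi-square (df=1) for a 2x2 table; ``(chi2, p)``.

    No continuity correction by default. ``correction=True`` applies the
    Yates correction ``(|ad-bc| - n/2)^2`` variant.
    """
    a, b, c, d = t.cells
    n = t.n
    margins = (a + b, c + d, a + c, b + d)
    if 0 in margins:
        raise ValidationError(f"zero margin in {t.cells}: chi-square undefined")
    diff = abs(a * d - b * c)
    if correction:
        diff = max(0.0, diff - n / 2)
    chi2 = n * diff * diff / (margins[0] * margins[1] * margins[2] * margins[3])
    p = float(chi2_dist.sf(chi2, df=1))
    return float(chi2), p


def analyze_table(
    t: Table2x2, *, haldane: bool = False, correction: bool = False
) -> ContingencyResult:
    """OR + Woolf CI, Fisher and chi-square p for one table.

    ``method_note`` marks which p a report should surface: Fisher when any
    expected cell count is below 5, chi-square otherwise. Both p-values are
    always computed and stored. The chi-square entry is ``None`` when a
    margin is zero.
    """
    try:
        or_, lo, hi = odds_ratio_woolf(t, haldane=haldane)
    except ZeroCellError:
        or_ = lo = hi = float("nan")  # zero cell, correction not requested
    p_fisher = fisher_exact_two_tailed(t)
    try:
        chi2, p_chi2 = pearson_chi2_2x2(t, correction=correction)
    except ValidationError:
        chi2 = p_chi2 = None
    note = "fisher" if t.expected().min() < 5 else "chi2"
    return ContingencyResult(
        table=t, or_=or_, ci_low=lo, ci_high=hi,
        p_fisher=p_fisher, chi2=chi2, p_chi2=p_chi2, method_note=note,
    )


def binomial_rate_ci(k: int, n: int) -> tuple[float, float, float]:
    """Event rate with exact Clopper–Pearson 95% CI; ``(rate, low, high)``."""
    if not 0 <= k <= n or n < 1:
        raise ValidationError(f"need 0 <= k <= n, n >= 1; got k={k}, n={n}")
    rate = k / n
    low = 0.0 if k == 0 else float(beta_dist.ppf(0.025, k, n - k + 1))
    high = 1.0 if k == n else float(beta_dist.ppf(0.975, k + 1, n - k))
    return rate, low, high


# ---------------------------------------------------------------------------
# Growth-rank stratification
# ---------------------------------------------------------------------------

@dataclass
class StrataSplit:
    """Contiguous serial-rank groups of clone IDs, fastest first."""

    groups: list[list[str]]
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.labels:
            self.labels = [f"group{i + 1}" for i in range(len(self.groups))]
        if len(self.labels) != len(self.groups):
            raise ValidationError("labels and groups differ in length")

    @property
    def sizes(self) -> list[int]:
        return [len(g) for g in self.groups]

    @property
    def boundaries(self) -> list[tuple[int, int]]:
        """1-based inclusive serial ranges of each group."""
        out = []
        start = 1
        for g in self.groups:
            out.append((start, start + len(g) - 1))
            start += len(g)
        return out

    def slow_vs_normal(self) -> tuple[list[str], list[str]]:
        """The slowest group versus the union of all faster groups."""
        if len(self.groups) < 2:
            raise ValidationError("need at least two groups")
        normal = [cid for g in self.groups[:-1] for cid in g]
        return self.groups[-1], normal


def split_by_rank(clone_ids: Sequence[str], n_groups: int) -> StrataSplit:
    """Cut a serially ordered cohort into contiguous (near-)equal blocks.

    A remainder of r clones goes to the first r groups, so blocks differ by
    at most one. For cohorts of 381 and 180 in three groups this yields
    ranks 1-127/128-254/255-381 and 1-60/61-120/121-180.
    """
    n = len(clone_ids)
    if n_groups < 2:
        raise ValidationError("n_groups must be >= 2")
    if n < n_groups:
        raise ValidationError(f"cohort of {n} cannot fill {n_groups} groups")
    base, rem = divmod(n, n_groups)
    groups = []
    start = 0
    for i in range(n_groups):
        size = base + (1 if i < rem else 0)
        groups.append(list(clone_ids[start:start + size]))
        start += size
    labels = (
        ["fast", "intermediate", "slow"] if n_groups == 3
        else [f"group{i + 1}" for i in range(n_groups)]
    )
    return StrataSplit(groups=groups, labels=labels)


def merge_similar_groups(
    split: StrataSplit,
    event_flags: Mapping[str, bool],
    alpha: float = 0.05,
) -> StrataSplit:
    """Merge adjacent fast groups while statistically indistinguishable.

    Starting from the fastest group, the next group is pooled in while the
    uncorrected chi-square p between the pooled block and that group
    exceeds ``alpha``; the slowest group is always kept separate. When
    everything but the slowest group merges, labels become
    ``["normal", "slow"]``.
    """
    if len(split.groups) < 3:
        raise ValidationError("merging needs at least three groups")

    def kn(ids: Sequence[str]) -> tuple[int, int]:
        k = sum(bool(event_flags.get(cid, False)) for cid in ids)
        return k, len(ids)

    merged = list(split.groups[0])
    out_groups: list[list[str]] = []
    for grp in split.groups[1:-1]:
        k1, n1 = kn(merged)
        k2, n2 = kn(grp)
        t = Table2x2(k1, n1 - k1, k2, n2 - k2)
        try:
            _, p = pearson_chi2_2x2(t)
        except ValidationError:  # both groups all-zero or all-one: identical
            p = 1.0
        if p > alpha:
            merged = merged + list(grp)
        else:
            out_groups.append(merged)
            merged = list(grp)
    out_groups.append(merged)
    out_groups.append(list(split.groups[-1]))
    if len(out_groups) == 2:
        labels = ["normal", "slow"]
    else:
        labels = [f"block{i + 1}" for i in range(len(out_groups) - 1)] + ["slow"]
    return StrataSplit(groups=out_groups, labels=labels)


def event_presence_table(
    event_flags: Mapping[str, bool], split: StrataSplit
) -> Table2x2:
    """Slow-vs-normal 2x2 of clones with/without an event.

    Cell layout: a/b = slow group with/without the event, c/d = pooled
    faster groups with/without.
    """
    slow, normal = split.slow_vs_normal()
    a = sum(bool(event_flags.get(cid, False)) for cid in slow)
    c = sum(bool(event_flags.get(cid, False)) for cid in normal)
    return Table2x2(a, len(slow) - a, c, len(normal) - c)


def burden_threshold_table(
    statuses: Sequence[ClonalStatus] | Mapping[str, int],
    split: StrataSplit,
    min_burden: int,
) -> Table2x2:
    """Slow-vs-normal 2x2 of clones with burden above ``min_burden``.

    a/b = slow clones with burden > min_burden / the rest; c/d likewise
    for the pooled faster groups.
    """
    if min_burden < 1:
        raise ValidationError("min_burden must be >= 1")
    if isinstance(statuses, Mapping):
        burdens = dict(statuses)
    else:
        burdens = {s.clone_id: s.burden for s in statuses}
    flags = {cid: burden > min_burden for cid, burden in burdens.items()}
    return event_presence_table(flags, split)
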