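"""Forward-time branching-process simulator for subclone STR cohorts.

Each simulated subclone descends from a single founder cell seeded by
limiting dilution and expands for ``divisions`` synchronous doublings.
During every division each STR locus may acquire an aberration — LOH at
loci heterozygous in the parental profile, a slippage (EMAST) shift of
±1 or ±2 repeat units at any locus, or loss of the amelogenin Y product —
with small per-division probabilities. An event arising at division ``d``
is carried by an expected fraction ``2**-d`` of the final culture, and it
reaches the typed profile only when that fraction is at least the
detectability threshold ``theta`` (capillary electrophoresis does not call
alleles carried by a small minority of the cells). With the default
``theta = 0.3`` only first-division events — and any pre-existing founder
event, at fraction 1 — are callable, while later events still accumulate
silently as true mutational burden.

Growth couples to burden multiplicatively: harvest time is
``base_time * fitness_cost**n_true_events`` times log-normal noise, so with
``fitness_cost > 1`` heavily mutated clones are picked later and the serial
pick rank becomes a growth-rate proxy with a built-in slow-growth /
high-burden association. ``fitness_cost = 1`` switches the coupling off.

Observable EMAST replaces the template parental allele with the shifted
allele in the profile (a clone-level substitution), LOH removes the lost
allele, and Y loss clears the amelogenin Y flag, so running the caller on a
simulated cohort recovers exactly the observable true events.

Randomness: one integer cohort seed; clone ``i`` uses the independent
stream ``default_rng([seed, i])``, keeping serial and parallel generation
byte-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .caller import AberrationEvent, EventType
from .errors import DataError, ValidationError
from .str_model import (
    AMELO,
    AlleleCall,
    LocusPanel,
    STRProfile,
    write_genotype_table,
)


@dataclass
class SimParams:
    """Cohort-generation parameters.

    Rates are per locus per division; defaults emulate a genetically
    unstable tumour line in which roughly one subclone in three acquires a
    callable aberration, against a detectability threshold that hides
    late-arising minority events.
    """

    mu_loh: float = 0.008        # per het locus per division
    mu_emast: float = 0.018      # per STR locus per division
    mu_yloss: float = 0.005      # per division
    locus_weights: Optional[dict[str, float]] = None  # EMAST rate multipliers
    divisions: int = 20          # founder -> harvested monolayer
    theta: float = 0.3           # min lineage fraction for a callable allele
    founder_aberrant_frac: float = 0.02  # founder already carries one event
    fitness_cost: float = 1.3    # growth delay factor per true event
    base_time: float = 1.0       # arbitrary harvest-time unit
    growth_noise_sd: float = 0.2  # sigma of log-normal harvest-time noise
    shift_probs: tuple[float, float] = (0.8, 0.2)  # P(|shift| = 1), P(= 2) units
    n_clones: int = 400
    seed: int = 0

    def validate(self) -> None:
        for name in ("mu_loh", "mu_emast", "mu_yloss", "founder_aberrant_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.theta <= 1.0:
            raise ValidationError(f"theta must be in (0, 1], got {self.theta}")
        if self.divisions < 1:
            raise ValidationError("divisions must be >= 1")
        if self.fitness_cost < 1.0:
            raise ValidationError("fitness_cost must be >= 1")
        if self.n_clones < 1:
            raise ValidationError("n_clones must be >= 1")
        if abs(sum(self.shift_probs) - 1.0) > 1e-9:
            raise ValidationError("shift_probs must sum to 1")


@dataclass(frozen=True)
class SimEvent:
    """Ground-truth event: the aberration plus its lineage bookkeeping."""

    event: AberrationEvent
    division: int           # 0 = pre-existing in the founder cell
    observable: bool        # lineage fraction 2**-division >= theta


@dataclass
class SimClone:
    """One simulated subclone with profile, truth, and growth ordinals."""

    profile: STRProfile
    true_events: list[SimEvent] = field(default_factory=list)
    growth_time: float = 0.0
    pick_rank: int = 0

    @property
    def observable_events(self) -> list[AberrationEvent]:
        return [se.event for se in self.true_events if se.observable]

    @property
    def n_true(self) -> int:
        return len(self.true_events)


def detectable_divisions(params: SimParams) -> int:
    """Number of post-founder divisions whose events are callable.

    An event at division d has lineage fraction 2**-d, so d is callable
    iff 2**-d >= theta, i.e. d <= floor(log2(1/theta)); theta above 0.5
    leaves only founder (division-0) events visible.
    """
    if params.theta > 0.5:
        return 0
    d = int(math.floor(math.log2(1.0 / params.theta) + 1e-9))
    return min(params.divisions, d)


# ---------------------------------------------------------------------------
# Single-clone simulation
# ---------------------------------------------------------------------------

def _draw_emast(
    rng: np.random.Generator,
    parent_alleles: frozenset[AlleleCall],
    current: frozenset[AlleleCall],
    shift_probs: Sequence[float],
) -> Optional[tuple[AlleleCall, AlleleCall, int]]:
    """Pick (template, novel, shift_units); None if no legal shift exists."""
    ref = sorted(parent_alleles)[rng.integers(len(parent_alleles))]
    mag = int(rng.choice([1, 2], p=list(shift_probs)))
    sign = int(rng.choice([-1, 1]))
    for s in (sign, -sign):
        units = s * mag
        if ref.repeats + units < 1:
            continue
        novel = ref.shifted(units)
        if novel not in parent_alleles and novel not in current:
            return ref, novel, units
    return None


def simulate_clone(
    parent: STRProfile,
    params: SimParams,
    panel: LocusPanel,
    rng: np.random.Generator,
    clone_id: str = "sim",
) -> SimClone:
    """Simulate one subclone expansion from the parental profile."""
    params.validate()
    str_loci = [l for l in panel.str_loci if l.name in parent.calls]
    het_loci = [l for l in str_loci if len(parent.calls[l.name]) >= 2]
    weights = params.locus_weights or {}
    d_max = detectable_divisions(params)

    calls = dict(parent.calls)
    amelo_y = parent.amelo_y
    touched: set[str] = set()
    events: list[SimEvent] = []

    def try_event(locus_name: str, etype: EventType, division: int) -> None:
        nonlocal amelo_y
        observable = division <= d_max
        if observable and locus_name in touched:
            return  # one callable event per locus: later ones are masked
        if etype is EventType.Y_LOSS:
            if not parent.amelo_y or (observable and not amelo_y):
                return
            ev = AberrationEvent(clone_id=clone_id, locus=AMELO,
                                 etype=EventType.Y_LOSS)
            if observable:
                amelo_y = False
                touched.add(AMELO)
        elif etype is EventType.LOH:
            alleles = sorted(parent.calls[locus_name])
            lost = alleles[rng.integers(len(alleles))]
            ev = AberrationEvent(clone_id=clone_id, locus=locus_name,
                                 etype=EventType.LOH, lost_allele=lost)
            if observable:
                calls[locus_name] = calls[locus_name] - {lost}
                touched.add(locus_name)
        else:  # EMAST
            unit = panel[locus_name].unit_nt
            drawn = _draw_emast(rng, parent.calls[locus_name],
                                calls[locus_name], params.shift_probs)
            if drawn is None:
                return
            ref, novel, units = drawn
            ev = AberrationEvent(
                clone_id=clone_id, locus=locus_name, etype=EventType.EMAST,
                novel_allele=novel, ref_allele=ref, shift_nt=units * unit,
            )
            if observable:
                calls[locus_name] = (calls[locus_name] - {ref}) | {novel}
                touched.add(locus_name)
        events.append(SimEvent(event=ev, division=division,
                               observable=observable))

    # Founder cell may already carry one aberration (division 0, fraction 1).
    if params.founder_aberrant_frac > 0 and rng.random() < params.founder_aberrant_frac:
        w_loh = params.mu_loh * len(het_loci)
        w_emast = params.mu_emast * len(str_loci)
        w_y = params.mu_yloss if parent.amelo_y else 0.0
        total = w_loh + w_emast + w_y
        if total > 0:
            u = rng.random() * total
            if u < w_loh:
                locus = het_loci[rng.integers(len(het_loci))]
                try_event(locus.name, EventType.LOH, 0)
            elif u < w_loh + w_emast:
                locus = str_loci[rng.integers(len(str_loci))]
                try_event(locus.name, EventType.EMAST, 0)
            else:
                try_event(AMELO, EventType.Y_LOSS, 0)

    for d in range(1, params.divisions + 1):
        if het_loci and params.mu_loh > 0:
            hits = rng.random(len(het_loci)) < params.mu_loh
            for locus, hit in zip(het_loci, hits):
                if hit:
                    try_event(locus.name, EventType.LOH, d)
        if params.mu_emast > 0:
            probs = np.array(
                [min(1.0, params.mu_emast * weights.get(l.name, 1.0))
                 for l in str_loci]
            )
            hits = rng.random(len(str_loci)) < probs
            for locus, hit in zip(str_loci, hits):
                if hit:
                    try_event(locus.name, EventType.EMAST, d)
        if parent.amelo_y and params.mu_yloss > 0 and rng.random() < params.mu_yloss:
            try_event(AMELO, EventType.Y_LOSS, d)

    noise = math.exp(rng.normal(0.0, params.growth_noise_sd))
    growth_time = params.base_time * params.fitness_cost ** len(events) * noise
    profile = STRProfile(clone_id=clone_id, calls=calls,
                         amelo_x=parent.amelo_x, amelo_y=amelo_y)
    return SimClone(profile=profile, true_events=events, growth_time=growth_time)


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def simulate_cohort(
    parent: STRProfile, params: SimParams, panel: LocusPanel
) -> list[SimClone]:
    """Simulate a cohort and order it by harvest time (pick rank).

    Clone IDs are assigned after sorting (``sim0001`` grew fastest), so the
    serial number mirrors the pick order, exactly as in a limiting-dilution
    experiment where wells are harvested as they reach confluence.
    """
    params.validate()
    clones = []
    for i in range(params.n_clones):
        rng = np.random.default_rng([params.seed, i])
        clones.append(simulate_clone(parent, params, panel, rng, clone_id=f"f{i}"))
    order = sorted(range(len(clones)), key=lambda i: (clones[i].growth_time, i))
    width = max(4, len(str(params.n_clones)))
    for rank, i in enumerate(order, start=1):
        clone = clones[i]
        clone.pick_rank = rank
        cid = f"sim{rank:0{width}d}"
        clone.profile.clone_id = cid
        clone.true_events = [
            SimEvent(
                event=AberrationEvent(
                    clone_id=cid, locus=se.event.locus, etype=se.event.etype,
                    lost_allele=se.event.lost_allele,
                    novel_allele=se.event.novel_allele,
                    ref_allele=se.event.ref_allele,
                    shift_nt=se.event.shift_nt,
                ),
                division=se.division,
                observable=se.observable,
            )
            for se in clone.true_events
        ]
    return [clones[i] for i in order]


def truth_to_frame(cohort: Sequence[SimClone]) -> pd.DataFrame:
    rows = []
    for clone in cohort:
        for se in clone.true_events:
            e = se.event
            rows.append(
                {
                    "clone_id": e.clone_id,
                    "locus": e.locus,
                    "etype": e.etype.value,
                    "lost_allele": str(e.lost_allele) if e.lost_allele else "",
                    "novel_allele": str(e.novel_allele) if e.novel_allele else "",
                    "ref_allele": str(e.ref_allele) if e.ref_allele else "",
                    "shift_nt": "" if e.shift_nt is None else e.shift_nt,
                    "division": se.division,
                    "observable": int(se.observable),
                }
            )
    cols = ["clone_id", "locus", "etype", "lost_allele", "novel_allele",
            "ref_allele", "shift_nt", "division", "observable"]
    return pd.DataFrame(rows, columns=cols)


def write_cohort(
    cohort: Sequence[SimClone],
    params: SimParams,
    panel: LocusPanel,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write genotypes.tsv (pipeline input), truth.tsv, and a params echo."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": out / "genotypes.tsv",
        "truth": out / "truth.tsv",
        "params": out / "params.yaml",
    }
    write_genotype_table([c.profile for c in cohort], paths["genotypes"], panel)
    truth_to_frame(cohort).to_csv(paths["truth"], sep="\t", index=False)
    echo = asdict(params)
    echo["shift_probs"] = list(params.shift_probs)
    paths["params"].write_text(yaml.safe_dump(echo, sort_keys=True))
    return paths


# ---------------------------------------------------------------------------
# Rate estimation (inversion of the observation model)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RateEstimate:
    """Method-of-moments per-locus per-division rate with bootstrap CI."""

    rate: float
    ci_low: float
    ci_high: float
    f_obs: float
    n_clones: int
    n_loci: int
    d_detect: int


def estimate_rates(
    n_aberrant: int,
    n_clones: int,
    n_informative_loci: int,
    params: SimParams,
    *,
    n_boot: int = 1000,
    rng: Optional[np.random.Generator] = None,
) -> RateEstimate:
    """Invert the aberrant-clone fraction into a per-locus per-division rate.

    Under the observation model a clone is callable-aberrant with
    probability ``1 - (1 - mu)**(L * d)`` where ``d`` is the number of
    detectable divisions, so the method-of-moments estimate is
    ``mu ≈ -ln(1 - f_obs) / (L * d)``. The CI is a percentile bootstrap
    over clones (binomial resampling of the aberrant flag). Assumes no
    pre-existing founder events (``founder_aberrant_frac = 0``).
    """
    if not 0 <= n_aberrant <= n_clones or n_clones < 1:
        raise ValidationError("need 0 <= n_aberrant <= n_clones, n_clones >= 1")
    if n_informative_loci < 1:
        raise ValidationError("n_informative_loci must be >= 1")
    f_obs = n_aberrant / n_clones
    if f_obs >= 1.0:
        raise DataError(
            "every clone is aberrant: the rate is not identifiable from "
            "a saturated cohort"
        )
    d = detectable_divisions(params)
    if d < 1:
        raise DataError(
            f"theta={params.theta} leaves no detectable division; "
            "the cohort carries no rate information"
        )
    denom = n_informative_loci * d

    def invert(f: float) -> float:
        return -math.log1p(-min(f, 1.0 - 1e-12)) / denom

    rate = invert(f_obs)
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    ks = rng.binomial(n_clones, f_obs, size=n_boot)
    boots = np.array([invert(k / n_clones) for k in ks])
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return RateEstimate(
        rate=rate, ci_low=float(lo), ci_high=float(hi),
        f_obs=f_obs, n_clones=n_clones, n_loci=n_informative_loci, d_detect=d,
    )


def expected_aberrant_fraction(
    params: SimParams, n_het_loci: int, n_str_loci: int, has_y: bool = True
) -> float:
    """Closed-form callable-aberrant clone fraction under the model.

    Per-division callable probability pools LOH (het loci), EMAST (all STR
    loci) and Y loss over the detectable divisions; founder events add
    ``founder_aberrant_frac`` on top.
    """
    d = detectable_divisions(params)
    p_keep = (
        (1.0 - params.mu_loh) ** (n_het_loci * d)
        * (1.0 - params.mu_emast) ** (n_str_loci * d)
        * ((1.0 - params.mu_yloss) ** d if has_y else 1.0)
    )
    p = 1.0 - p_keep
    return params.founder_aberrant_frac + (1.0 - params.founder_aberrant_frac) * p
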