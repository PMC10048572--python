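"""Calling STR aberrations in clone profiles against a designated parent.

Two somatic event classes are called at repeat loci, following the standard
taxonomy for tumour STR profiling:

* **LOH** — loss of heterozygosity: one of two (or more) distinct parental
  alleles disappears with no replacement product.
* **EMAST** — elevated microsatellite alteration at selected tetranucleotide
  repeats: a novel allele appears whose repeat-region length differs from a
  parental allele by a nonzero whole number of repeat units (slippage-type
  insertion/deletion).

At the amelogenin sex marker, disappearance of the Y product is called as a
distinct **Y_LOSS** event. A novel allele that is not a whole-unit shift
from any parental allele within the configured window has no place in this
taxonomy and is reported as **UNCLASSIFIED**; such events are excluded from
the LOH/EMAST tallies and from the clone burden.

Precedence between the two classes at one locus: when a parental allele is
missing *and* a novel allele lies within the shift window of it, the pair
is one EMAST (allele shift), not LOH plus gain. Attribution of novel
alleles to missing parental alleles uses an exhaustive optimal matching —
maximise matched pairs, then minimise total absolute shift, then prefer the
shorter parental allele — which keeps the output deterministic and
well-defined for tri-allelic patterns. Loci homozygous in the parent can
never yield LOH; they stay informative for EMAST only.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import (
    DataError,
    NullProfileError,
    StructuralMismatchError,
    ValidationError,
)
from .str_model import AMELO, AlleleCall, LocusPanel, STRProfile

#: Default attribution window, in repeat units, for pairing a novel allele
#: with a parental allele.
DEFAULT_SHIFT_WINDOW = 2


class EventType(str, Enum):
    LOH = "LOH"
    EMAST = "EMAST"
    Y_LOSS = "Y_LOSS"
    UNCLASSIFIED = "UNCLASSIFIED"


@dataclass(frozen=True)
class AberrationEvent:
    """One called difference between a clone and its designated parent.

    ``ref_allele`` is the parental allele an EMAST shift is computed
    against ("EMAST +4 nt at allele 14"); ``ambiguous_ref`` flags that the
    novel allele was equidistant from two parental alleles and the shorter
    one was chosen.
    """

    clone_id: str
    locus: str
    etype: EventType
    lost_allele: Optional[AlleleCall] = None
    novel_allele: Optional[AlleleCall] = None
    ref_allele: Optional[AlleleCall] = None
    shift_nt: Optional[int] = None
    ambiguous_ref: bool = False

    def signature(self) -> tuple:
        """Identity of the event irrespective of the clone carrying it."""
        return (self.locus, self.etype, self.lost_allele, self.novel_allele,
                self.shift_nt)


@dataclass(frozen=True)
class ClonalStatus:
    """Per-clone aberration tally.

    ``burden`` counts LOH + EMAST + Y_LOSS events; UNCLASSIFIED events are
    tracked separately and do not enter the burden, so ``stable`` means
    "no event of the three recognised classes".
    """

    clone_id: str
    stable: bool
    n_loh: int
    n_emast: int
    n_yloss: int
    n_unclassified: int = 0

    @property
    def burden(self) -> int:
        return self.n_loh + self.n_emast + self.n_yloss


# ---------------------------------------------------------------------------
# Profile comparison
# ---------------------------------------------------------------------------

def _match_novel_to_missing(
    novel: Sequence[AlleleCall],
    missing: Sequence[AlleleCall],
    unit: int,
    window_nt: int,
) -> dict[AlleleCall, AlleleCall]:
    """Optimal assignment of novel alleles to missing parental alleles.

    A pair is admissible when the length difference is a nonzero multiple
    of the repeat unit no larger than the window. Among assignments with
    the most pairs, the one with the smallest total |shift| wins; remaining
    ties prefer shorter parental alleles (deterministic output).
    """
    if not novel or not missing:
        return {}

    def admissible(nv: AlleleCall, m: AlleleCall) -> bool:
        d = nv.length_nt(unit) - m.length_nt(unit)
        return d != 0 and d % unit == 0 and abs(d) <= window_nt

    slots: list[Optional[AlleleCall]] = list(missing) + [None] * len(novel)
    best_key = None
    best: dict[AlleleCall, AlleleCall] = {}
    for perm in itertools.permutations(slots, len(novel)):
        pairs = []
        ok = True
        for nv, m in zip(novel, perm):
            if m is None:
                continue
            if not admissible(nv, m):
                ok = False
                break
            pairs.append((nv, m))
        if not ok:
            continue
        total_shift = sum(
            abs(nv.length_nt(unit) - m.length_nt(unit)) for nv, m in pairs
        )
        # pair-length tuple totally orders distinct outcomes, so ties in
        # count and total shift resolve to the shorter parental allele
        pair_lengths = tuple(
            sorted((m.length_nt(unit), nv.length_nt(unit)) for nv, m in pairs)
        )
        key = (-len(pairs), total_shift, pair_lengths)
        if best_key is None or key < best_key:
            best_key = key
            best = dict(pairs)
    return best


def _nearest_parent(
    novel: AlleleCall, candidates: Sequence[AlleleCall], unit: int
) -> tuple[AlleleCall, bool]:
    """Nearest candidate by length; ties go to the shorter allele."""
    ordered = sorted(candidates)
    dists = [abs(novel.length_nt(unit) - c.length_nt(unit)) for c in ordered]
    dmin = min(dists)
    hits = [c for c, d in zip(ordered, dists) if d == dmin]
    return hits[0], len(hits) > 1


def compare_profiles(
    parent: STRProfile,
    child: STRProfile,
    panel: LocusPanel,
    *,
    shift_window: int = DEFAULT_SHIFT_WINDOW,
) -> list[AberrationEvent]:
    """Call aberration events in ``child`` relative to ``parent``.

    Events are returned in panel order (STR loci first, amelogenin last);
    within a locus LOH events precede EMAST, then UNCLASSIFIED, each sorted
    by allele. ``compare_profiles(p, p)`` is always empty.

    Raises :class:`StructuralMismatchError` if the child types a locus the
    parent does not, and :class:`NullProfileError` for a locus where every
    parental allele is gone with nothing novel (amplification dropout).
    """
    extra = set(child.calls) - set(parent.calls)
    if extra:
        raise StructuralMismatchError(
            f"{child.clone_id}: loci typed in child but not in parent "
            f"{parent.clone_id}: {sorted(extra)}"
        )
    events: list[AberrationEvent] = []
    for locus_def in panel.str_loci:
        locus = locus_def.name
        if locus not in parent.calls or locus not in child.calls:
            continue
        P = parent.calls[locus]
        C = child.calls[locus]
        if not C:
            raise NullProfileError(
                f"{child.clone_id}: no alleles at {locus} (locus dropout)"
            )
        if C == P:
            continue
        unit = locus_def.unit_nt
        window_nt = shift_window * unit
        novel = sorted(C - P)
        missing = sorted(P - C)
        matched = _match_novel_to_missing(novel, missing, unit, window_nt)

        loh_events, emast_events, other_events = [], [], []
        for nv in novel:
            if nv in matched:
                ref = matched[nv]
                ambiguous = False
            else:
                surviving = sorted(P & C)
                ref, ambiguous = _nearest_parent(nv, surviving or sorted(P), unit)
            d = nv.length_nt(unit) - ref.length_nt(unit)
            if d != 0 and d % unit == 0 and abs(d) <= window_nt:
                emast_events.append(
                    AberrationEvent(
                        clone_id=child.clone_id,
                        locus=locus,
                        etype=EventType.EMAST,
                        novel_allele=nv,
                        ref_allele=ref,
                        shift_nt=d,
                        ambiguous_ref=ambiguous,
                    )
                )
            else:
                other_events.append(
                    AberrationEvent(
                        clone_id=child.clone_id,
                        locus=locus,
                        etype=EventType.UNCLASSIFIED,
                        novel_allele=nv,
                        ref_allele=ref,
                        ambiguous_ref=ambiguous,
                    )
                )
        consumed = set(matched.values())
        for m in missing:
            if m in consumed:
                continue
            if len(P) >= 2:
                loh_events.append(
                    AberrationEvent(
                        clone_id=child.clone_id,
                        locus=locus,
                        etype=EventType.LOH,
                        lost_allele=m,
                    )
                )
            # parent homozygous: the lone allele can only vanish alongside a
            # novel replacement (EMAST/UNCLASSIFIED above) or as dropout.
        events.extend(sorted(loh_events, key=lambda e: e.lost_allele))
        events.extend(sorted(emast_events, key=lambda e: e.novel_allele))
        events.extend(sorted(other_events, key=lambda e: e.novel_allele))

    if parent.amelo_y and not child.amelo_y:
        events.append(
            AberrationEvent(
                clone_id=child.clone_id, locus=AMELO, etype=EventType.Y_LOSS
            )
        )
    return events


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def classify_clone(
    events: Sequence[AberrationEvent], clone_id: Optional[str] = None
) -> ClonalStatus:
    """Tally one clone's events into a :class:`ClonalStatus`."""
    ids = {e.clone_id for e in events}
    if len(ids) > 1:
        raise ValidationError(f"events from multiple clones: {sorted(ids)}")
    if clone_id is None:
        clone_id = next(iter(ids)) if ids else ""
    elif ids and ids != {clone_id}:
        raise ValidationError(
            f"events belong to {sorted(ids)}, not {clone_id!r}"
        )
    n_loh = sum(e.etype is EventType.LOH for e in events)
    n_emast = sum(e.etype is EventType.EMAST for e in events)
    n_yloss = sum(e.etype is EventType.Y_LOSS for e in events)
    n_other = sum(e.etype is EventType.UNCLASSIFIED for e in events)
    return ClonalStatus(
        clone_id=clone_id,
        stable=(n_loh + n_emast + n_yloss) == 0,
        n_loh=n_loh,
        n_emast=n_emast,
        n_yloss=n_yloss,
        n_unclassified=n_other,
    )


def exclude_parental_loci(
    events: Iterable[AberrationEvent], excluded: Iterable[str]
) -> list[AberrationEvent]:
    """Drop events at the given loci (use :data:`AMELO` for Y loss).

    This is the second-step analysis filter: lesions already present in
    the parental clone are removed before re-tallying.
    """
    excluded = set(excluded)
    return [e for e in events if e.locus not in excluded]


def call_cohort(
    profiles: Sequence[STRProfile],
    parent: STRProfile,
    panel: LocusPanel,
    *,
    shift_window: int = DEFAULT_SHIFT_WINDOW,
    excluded_loci: Iterable[str] = (),
) -> tuple[list[AberrationEvent], list[ClonalStatus]]:
    """Compare every non-parent profile to the parent and tally statuses.

    Returns the flat event list (cohort order, then panel order) and one
    status per clone, in input order.
    """
    excluded = set(excluded_loci)
    all_events: list[AberrationEvent] = []
    statuses: list[ClonalStatus] = []
    for prof in profiles:
        if prof.clone_id == parent.clone_id:
            continue
        ev = compare_profiles(parent, prof, panel, shift_window=shift_window)
        if excluded:
            ev = exclude_parental_loci(ev, excluded)
        all_events.extend(ev)
        statuses.append(classify_clone(ev, prof.clone_id))
    return all_events, statuses


def per_locus_frequency(
    events: Iterable[AberrationEvent],
    cohort_size: int,
    etype: EventType | str,
    panel: LocusPanel,
    reference: Optional[STRProfile] = None,
) -> pd.DataFrame:
    """Per-locus event counts and cohort fractions for one event type.

    The returned frame covers every panel locus (zero-filled), with a
    ``homozygous_in_reference`` flag when a reference profile is given —
    loci homozygous in the control are informative for EMAST only, so
    their LOH rows are structurally zero.
    """
    etype = EventType(etype)
    if cohort_size < 1:
        raise ValidationError("cohort_size must be >= 1")
    counts: dict[str, int] = {l.name: 0 for l in panel}
    for e in events:
        if e.etype is etype:
            counts[e.locus] = counts.get(e.locus, 0) + 1
    rows = []
    for locus in panel:
        homo = (
            reference is not None
            and not locus.is_amelogenin
            and len(reference.calls.get(locus.name, frozenset())) == 1
        )
        rows.append(
            {
                "locus": locus.name,
                "count": counts[locus.name],
                "fraction": counts[locus.name] / cohort_size,
                "homozygous_in_reference": homo,
            }
        )
    return pd.DataFrame(rows)


def find_shared_profiles(
    events: Iterable[AberrationEvent], *, min_size: int = 2
) -> list[list[str]]:
    """Group aberrant clones whose event sets are exactly identical.

    Returns groups of clone IDs (sorted within and across groups) with at
    least ``min_size`` members; stable clones carry no events and are
    never grouped. Identical sibling subclones descending from one already
    aberrant founder cell surface here.
    """
    by_clone: dict[str, set[tuple]] = {}
    for e in events:
        by_clone.setdefault(e.clone_id, set()).add(e.signature())
    by_pattern: dict[frozenset, list[str]] = {}
    for clone_id, sigs in by_clone.items():
        by_pattern.setdefault(frozenset(sigs), []).append(clone_id)
    groups = [sorted(g) for g in by_pattern.values() if len(g) >= min_size]
    return sorted(groups)


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------

def events_to_frame(events: Iterable[AberrationEvent]) -> pd.DataFrame:
    rows = [
        {
            "clone_id": e.clone_id,
            "locus": e.locus,
            "etype": e.etype.value,
            "lost_allele": str(e.lost_allele) if e.lost_allele else "",
            "novel_allele": str(e.novel_allele) if e.novel_allele else "",
            "ref_allele": str(e.ref_allele) if e.ref_allele else "",
            "shift_nt": "" if e.shift_nt is None else e.shift_nt,
            "ambiguous_ref": int(e.ambiguous_ref),
        }
        for e in events
    ]
    cols = [
        "clone_id", "locus", "etype", "lost_allele", "novel_allele",
        "ref_allele", "shift_nt", "ambiguous_ref",
    ]
    return pd.DataFrame(rows, columns=cols)


def statuses_to_frame(statuses: Iterable[ClonalStatus]) -> pd.DataFrame:
    rows = [
        {
            "clone_id": s.clone_id,
            "stable": int(s.stable),
            "n_loh": s.n_loh,
            "n_emast": s.n_emast,
            "n_yloss": s.n_yloss,
            "n_unclassified": s.n_unclassified,
            "burden": s.burden,
        }
        for s in statuses
    ]
    cols = [
        "clone_id", "stable", "n_loh", "n_emast", "n_yloss",
        "n_unclassified", "burden",
    ]
    return pd.DataFrame(rows, columns=cols)


def read_status_table(path) -> list[ClonalStatus]:
    """Read a status TSV written from :func:`statuses_to_frame`."""
    df = pd.read_csv(path, sep="\t", dtype={"clone_id": str})
    required = {"clone_id", "n_loh", "n_emast", "n_yloss"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"status table {path} lacks columns {sorted(missing)}")
    out = []
    for row in df.itertuples():
        n_loh, n_emast, n_yloss = int(row.n_loh), int(row.n_emast), int(row.n_yloss)
        out.append(
            ClonalStatus(
                clone_id=row.clone_id,
                stable=(n_loh + n_emast + n_yloss) == 0,
                n_loh=n_loh,
                n_emast=n_emast,
                n_yloss=n_yloss,
                n_unclassified=int(getattr(row, "n_unclassified", 0)),
            )
        )
    return out
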