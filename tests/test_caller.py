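"""Aberration calling: worked examples, errors, aggregation, oracle parity."""

import itertools

import numpy as np
import pytest

import strclone as sc
from strclone.caller import EventType
from strclone.errors import (
    NullProfileError,
    StructuralMismatchError,
    ValidationError,
)
from strclone.str_model import AlleleCall, LocusDef, LocusPanel, STRProfile

from conftest import child_of


# ---------------------------------------------------------------------------
# Brute-force oracle: enumerate every novel<->missing pairing and apply the
# LOH/EMAST definitions literally (maximise pairs, then minimise total
# absolute shift, then prefer the shorter parental allele).
# ---------------------------------------------------------------------------

def oracle_locus_events(parent_set, child_set, unit, window_units=2):
    window = window_units * unit
    length = lambda a: a.length_nt(unit)
    novel = sorted(child_set - parent_set)
    missing = sorted(parent_set - child_set)

    def admissible(nv, m):
        d = length(nv) - length(m)
        return d != 0 and d % unit == 0 and abs(d) <= window

    candidates = []
    for k in range(min(len(novel), len(missing)), -1, -1):
        for nv_sub in itertools.combinations(novel, k):
            for m_perm in itertools.permutations(missing, k):
                pairs = list(zip(nv_sub, m_perm))
                if all(admissible(nv, m) for nv, m in pairs):
                    candidates.append(pairs)
        if candidates:
            break
    if candidates:
        pairs = min(
            candidates,
            key=lambda ps: (
                sum(abs(length(nv) - length(m)) for nv, m in ps),
                sorted((length(m), length(nv)) for nv, m in ps),
            ),
        )
    else:
        pairs = []
    matched_novel = {nv for nv, _ in pairs}
    matched_missing = {m for _, m in pairs}

    events = []
    for m in missing:
        if m not in matched_missing and len(parent_set) >= 2:
            events.append(("LOH", None, m, None))
    for nv, m in pairs:
        events.append(("EMAST", nv, None, length(nv) - length(m)))
    for nv in sorted(novel):
        if nv in matched_novel:
            continue
        targets = sorted(parent_set & child_set) or sorted(parent_set)
        dists = [abs(length(nv) - length(t)) for t in targets]
        ref = targets[dists.index(min(dists))]
        d = length(nv) - length(ref)
        if d != 0 and d % unit == 0 and abs(d) <= window:
            events.append(("EMAST", nv, None, d))
        else:
            events.append(("UNCLASSIFIED", nv, None, None))
    return sorted(events, key=repr)


def impl_locus_events(parent_set, child_set, unit):
    panel = LocusPanel([LocusDef("L1", "1p1", unit)])
    parent = STRProfile("p", {"L1": frozenset(parent_set)})
    child = STRProfile("c", {"L1": frozenset(child_set)})
    events = sc.compare_profiles(parent, child, panel)
    simplified = [
        (e.etype.value, e.novel_allele, e.lost_allele,
         e.shift_nt if e.etype is EventType.EMAST else None)
        for e in events
    ]
    return sorted(simplified, key=repr)


class TestCompareProfiles:
    def test_loh_at_heterozygous_locus(self, panel, jurkat):
        child = child_of(jurkat, D12S391="22")
        events = sc.compare_profiles(jurkat, child, panel)
        assert len(events) == 1
        e = events[0]
        assert e.etype is EventType.LOH
        assert e.locus == "D12S391"
        assert str(e.lost_allele) == "23"
        assert e.novel_allele is None

    @pytest.mark.parametrize(
        "child_alleles,novel,ref,shift",
        [("15,16", "15", "14", +4), ("12,16", "12", "14", -8)],
    )
    def test_emast_shift_at_allele_14(self, panel, jurkat, child_alleles,
                                      novel, ref, shift):
        child = child_of(jurkat, D10S1248=child_alleles)
        events = sc.compare_profiles(jurkat, child, panel)
        assert len(events) == 1
        e = events[0]
        assert e.etype is EventType.EMAST
        assert (str(e.novel_allele), str(e.ref_allele), e.shift_nt) == (
            novel, ref, shift,
        )

    def test_identical_profiles_yield_no_events(self, panel, jurkat, wil2s):
        assert sc.compare_profiles(jurkat, jurkat, panel) == []
        assert sc.compare_profiles(wil2s, wil2s, panel) == []

    def test_homozygous_parent_locus_yields_emast_never_loh(self, panel, jurkat):
        assert jurkat.calls["vWA"] == sc.parse_allele_set("18")
        same = child_of(jurkat, vWA="18")
        assert sc.compare_profiles(jurkat, same, panel) == []
        shifted = child_of(jurkat, vWA="17")
        events = sc.compare_profiles(jurkat, shifted, panel)
        assert [e.etype for e in events] == [EventType.EMAST]
        assert events[0].shift_nt == -4

    def test_y_loss_called_at_amelogenin(self, panel, jurkat):
        child = child_of(jurkat, amelo_y=False)
        events = sc.compare_profiles(jurkat, child, panel)
        assert [(e.locus, e.etype) for e in events] == [(sc.AMELO, EventType.Y_LOSS)]

    def test_missing_plus_nearby_novel_is_single_emast_not_loh(self, panel, jurkat):
        # parent D10S1248 {14,16}; allele 16 replaced by 15: one EMAST vs 16
        child = child_of(jurkat, D10S1248="14,15")
        events = sc.compare_profiles(jurkat, child, panel)
        assert len(events) == 1
        assert events[0].etype is EventType.EMAST
        assert (str(events[0].ref_allele), events[0].shift_nt) == ("16", -4)

    def test_novel_outside_window_leaves_loh_plus_unclassified(self, panel, jurkat):
        # 26 is +10 repeats from 16: no unit-window pairing exists
        child = child_of(jurkat, D10S1248="16,26")
        events = sc.compare_profiles(jurkat, child, panel)
        kinds = [(e.etype, str(e.lost_allele or ""), str(e.novel_allele or ""))
                 for e in events]
        assert (EventType.LOH, "14", "") in kinds
        assert (EventType.UNCLASSIFIED, "", "26") in kinds

    def test_tri_allelic_tie_attributes_to_shorter_parental(self, panel, jurkat):
        # novel 15 equidistant from surviving 14 and 16
        child = child_of(jurkat, D10S1248="14,15,16")
        events = sc.compare_profiles(jurkat, child, panel)
        assert len(events) == 1
        e = events[0]
        assert e.etype is EventType.EMAST
        assert str(e.ref_allele) == "14"
        assert e.shift_nt == +4
        assert e.ambiguous_ref

    def test_events_reported_in_panel_order(self, panel, jurkat):
        child = child_of(jurkat, vWA="17", D2S441="15", amelo_y=False)
        loci = [e.locus for e in sc.compare_profiles(jurkat, child, panel)]
        assert loci == ["D2S441", "vWA", sc.AMELO]

    def test_child_only_locus_is_structural_mismatch(self, panel, jurkat):
        child = child_of(jurkat)
        parent = STRProfile("p", {k: v for k, v in jurkat.calls.items()
                                  if k != "TH01"}, True, True)
        with pytest.raises(StructuralMismatchError, match="TH01"):
            sc.compare_profiles(parent, child, panel)

    def test_locus_dropout_is_null_profile_error(self, panel, jurkat):
        child = child_of(jurkat)
        child.calls["TH01"] = frozenset()
        with pytest.raises(NullProfileError, match="TH01"):
            sc.compare_profiles(jurkat, child, panel)


class TestOracleParity:
    def test_matches_bruteforce_on_random_small_profiles(self):
        rng = np.random.default_rng(42)
        for trial in range(400):
            unit = int(rng.choice([3, 4]))
            parent = frozenset(
                AlleleCall(int(r), int(rng.integers(0, unit)))
                for r in rng.choice(np.arange(8, 20), size=rng.integers(1, 4),
                                    replace=False)
            )
            pool = list(parent) + [
                AlleleCall(int(rng.integers(5, 24)), int(rng.integers(0, unit)))
                for _ in range(3)
            ]
            size = int(rng.integers(1, 4))
            idx = rng.choice(len(pool), size=size, replace=False)
            child = frozenset(pool[i] for i in idx)
            assert impl_locus_events(parent, child, unit) == oracle_locus_events(
                parent, child, unit
            ), (parent, child, unit)

    def test_self_comparison_empty_for_random_profiles(self):
        rng = np.random.default_rng(7)
        panel = sc.load_panel()
        for _ in range(20):
            calls = {
                l.name: frozenset(
                    AlleleCall(int(r))
                    for r in rng.choice(np.arange(6, 25),
                                        size=rng.integers(1, 4), replace=False)
                )
                for l in panel.str_loci
            }
            prof = STRProfile("p", calls, True, True)
            assert sc.compare_profiles(prof, prof, panel) == []

    def test_adding_novel_allele_at_clean_locus_preserves_events(self, panel, jurkat):
        child = child_of(jurkat, D12S391="22", vWA="17")
        before = sc.compare_profiles(jurkat, child, panel)
        richer = child_of(child, clone_id="child", D2S441="15,16,17")
        after = sc.compare_profiles(jurkat, richer, panel)
        before_sigs = {e.signature() for e in before}
        after_sigs = {e.signature() for e in after}
        assert before_sigs <= after_sigs
        assert any(e.locus == "D2S441" for e in after)


class TestAggregation:
    def _events(self, jurkat, panel, **loci):
        return sc.compare_profiles(jurkat, child_of(jurkat, **loci), panel)

    def test_classify_empty_is_stable(self):
        status = sc.classify_clone([], clone_id="c0")
        assert status.stable and status.burden == 0

    def test_classify_counts_by_type(self, panel, jurkat):
        child = child_of(jurkat, D12S391="22", D10S1248="15,16", amelo_y=False)
        status = sc.classify_clone(sc.compare_profiles(jurkat, child, panel))
        assert (status.n_loh, status.n_emast, status.n_yloss) == (1, 1, 1)
        assert status.burden == 3 and not status.stable

    def test_classify_multi_locus_burdens(self, panel, jurkat):
        five_loh = child_of(jurkat, D12S391="22", D18S51="21", FGA="20.2",
                            D13S317="8", D7S820="8")
        status = sc.classify_clone(sc.compare_profiles(jurkat, five_loh, panel))
        assert status.n_loh == 5 and status.burden == 5
        six_emast = child_of(jurkat, TH01="5,9.3", TPOX="8,11", D2S441="15,17",
                             D10S1248="13,16", D12S391="21,23", FGA="19.2,21.2")
        status = sc.classify_clone(sc.compare_profiles(jurkat, six_emast, panel))
        assert status.n_emast == 6 and status.burden == 6

    def test_classify_rejects_mixed_clones(self, panel, jurkat):
        e1 = self._events(jurkat, panel, D12S391="22")
        e2 = sc.compare_profiles(jurkat, child_of(jurkat, clone_id="other",
                                                  D12S391="22"), panel)
        with pytest.raises(ValidationError):
            sc.classify_clone(e1 + e2)

    def test_unclassified_events_do_not_enter_burden(self, panel, jurkat):
        child = child_of(jurkat, D10S1248="16,26")  # LOH 14 + unclassified 26
        status = sc.classify_clone(sc.compare_profiles(jurkat, child, panel))
        assert status.n_unclassified == 1
        assert status.burden == status.n_loh == 1

    def test_exclude_parental_loci(self, panel, jurkat):
        child = child_of(jurkat, D12S391="22", TH01="5,9.3", amelo_y=False)
        events = sc.compare_profiles(jurkat, child, panel)
        kept = sc.exclude_parental_loci(events, {"D12S391", sc.AMELO})
        assert [(e.locus, e.etype) for e in kept] == [("TH01", EventType.EMAST)]
        assert sc.exclude_parental_loci(events, set()) == events
        assert sc.exclude_parental_loci(kept, {"TH01"}) == []

    def test_per_locus_frequency(self, panel, jurkat):
        events = self._events(jurkat, panel, D10S1248="14")
        table = sc.per_locus_frequency(events, 350, "LOH", panel, reference=jurkat)
        row = table.set_index("locus").loc["D10S1248"]
        assert row["count"] == 1
        assert row["fraction"] == pytest.approx(1 / 350)
        assert table["count"].sum() == 1
        assert table.set_index("locus").loc["vWA", "homozygous_in_reference"]
        assert not table.set_index("locus").loc["D12S391", "homozygous_in_reference"]

    def test_per_locus_frequency_zero_events_and_bad_type(self, panel, jurkat):
        table = sc.per_locus_frequency([], 10, EventType.EMAST, panel)
        assert (table["count"] == 0).all()
        with pytest.raises(ValueError):
            sc.per_locus_frequency([], 10, "INDEL", panel)

    def test_find_shared_profiles(self, panel, jurkat):
        twins = [
            child_of(jurkat, clone_id=f"twin{i}", D12S391="22", D18S51="21",
                     FGA="20.2", D13S317="8", D7S820="8")
            for i in range(2)
        ]
        triplets = [
            child_of(jurkat, clone_id=f"tri{i}", TH01="5,9.3", TPOX="8,11",
                     D2S441="15,17", D10S1248="13,16", D12S391="21,23")
            for i in range(3)
        ]
        singleton = child_of(jurkat, clone_id="solo", D12S391="22")
        stable = child_of(jurkat, clone_id="stable")
        events, statuses = sc.call_cohort(
            twins + triplets + [singleton, stable], jurkat, panel
        )
        groups = sc.find_shared_profiles(events)
        assert groups == [["tri0", "tri1", "tri2"], ["twin0", "twin1"]]
        assert sc.find_shared_profiles([]) == []
        # count consistency across the cohort
        assert sum(s.stable for s in statuses) + sum(
            not s.stable for s in statuses
        ) == len(statuses) == 7
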