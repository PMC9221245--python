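import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from minisplice.acmg import (
    EvidenceStrength,
    InSilicoAnnotation,
    RuleConfig,
    Strength,
    TranscriptCall,
    TranscriptEvidence,
    aggregate_readout,
    classify,
    format_evidence,
    pm2_evidence,
    transcript_evidence,
)
from minisplice.errors import EvidenceError, InputError


def te(fraction, call, label="t"):
    return TranscriptEvidence(label, fraction, call)


# ---------------------------------------------------------------------------
# independent brute-force rule evaluator, deliberately written from scratch
# ---------------------------------------------------------------------------

_STRENGTH_POINTS = {"supporting": 1, "moderate": 2, "strong": 4, "very_strong": 8}
_CALL_TABLE = {
    TranscriptCall.P_VS: ("pathogenic", "very_strong"),
    TranscriptCall.P_S: ("pathogenic", "strong"),
    TranscriptCall.P_M: ("pathogenic", "moderate"),
    TranscriptCall.P_P: ("pathogenic", "supporting"),
    TranscriptCall.B_S: ("benign", "strong"),
    TranscriptCall.B_P: ("benign", "supporting"),
    TranscriptCall.NA: ("none", None),
}


def oracle_aggregate(items):
    """Exhaustive restatement of the share rules: returns (direction, points)."""
    frac = {}
    for it in items:
        direction, strength = _CALL_TABLE[it.call]
        frac.setdefault(direction, []).append((it.fraction_percent, strength))
    for direction, sign in (("pathogenic", +1), ("benign", -1)):
        members = frac.get(direction, [])
        share = sum(f for f, _ in members)
        if share >= 90.0:
            big = [s for f, s in members if f > 10.0]
            pool = big if big else [s for _, s in members]
            weakest = min(pool, key=lambda s: _STRENGTH_POINTS[s])
            return direction, sign * _STRENGTH_POINTS[weakest]
    return "none", 0


class TestTranscriptEvidence:
    def test_ptc_nmd_very_strong(self):
        assert transcript_evidence("PTC_NMD", 95.0).call is TranscriptCall.P_VS

    def test_ptc_escape_strong_without_critical_domain(self):
        assert transcript_evidence("PTC_escape", 50.0).call is TranscriptCall.P_S

    def test_ptc_escape_upgraded_on_critical_domain(self):
        ev = transcript_evidence("PTC_escape", 100.0, critical_domain_lost=True)
        assert ev.call is TranscriptCall.P_VS

    def test_upgrade_can_be_disabled(self):
        rules = RuleConfig(ptc_escape_critical_upgrade=False)
        ev = transcript_evidence(
            "PTC_escape", 100.0, critical_domain_lost=True, rules=rules
        )
        assert ev.call is TranscriptCall.P_S

    def test_in_frame_critical_domain_very_strong(self):
        ev = transcript_evidence("in_frame", 95.3, critical_domain_lost=True)
        assert ev.call is TranscriptCall.P_VS

    def test_in_frame_deleterious_insilico_supporting(self):
        ev = transcript_evidence(
            "in_frame", 79.4, insilico=InSilicoAnnotation(provean_score=-11.94)
        )
        assert ev.call is TranscriptCall.P_P

    def test_in_frame_no_evidence(self):
        assert transcript_evidence("in_frame", 10.0).call is TranscriptCall.NA

    def test_wild_type_full_length_benign_strong(self):
        ev = transcript_evidence("FL", 26.3, variant_on_transcript=False)
        assert ev.call is TranscriptCall.B_S

    def test_missense_full_length_unsupportive_insilico(self):
        ev = transcript_evidence(
            "FL", 2.4, variant_on_transcript=True,
            insilico=InSilicoAnnotation(revel_score=0.5),
        )
        assert ev.call is TranscriptCall.NA

    def test_uncharacterized_no_evidence(self):
        assert transcript_evidence("uncharacterized", 4.7).call is TranscriptCall.NA

    def test_unknown_category_raises(self):
        with pytest.raises(EvidenceError):
            transcript_evidence("mystery", 50.0)

    def test_fraction_bounds(self):
        with pytest.raises(InputError):
            te(120.0, TranscriptCall.P_VS)


class TestAggregateExamples:
    def test_mixed_strengths_lowest_above_floor(self):
        items = [
            te(73.8, TranscriptCall.P_VS),
            te(25.1, TranscriptCall.P_P),
            te(1.1, TranscriptCall.NA),
        ]
        ev = aggregate_readout(items)
        assert (ev.code, ev.strength, ev.points) == ("PVS1_O", Strength.SUPPORTING, 1)

    def test_minor_weak_transcript_below_floor_ignored(self):
        items = [te(94.8, TranscriptCall.P_VS), te(5.2, TranscriptCall.P_P)]
        ev = aggregate_readout(items)
        assert (ev.strength, ev.points) == (Strength.VERY_STRONG, 8)

    def test_benign_fraction_blocks_code(self):
        items = [te(78.7, TranscriptCall.P_VS), te(21.3, TranscriptCall.B_S)]
        ev = aggregate_readout(items)
        assert (ev.strength, ev.points) == (Strength.NOT_APPLICABLE, 0)

    def test_single_transcript(self):
        ev = aggregate_readout([te(100.0, TranscriptCall.P_VS)])
        assert (ev.code, ev.strength) == ("PVS1_O", Strength.VERY_STRONG)

    def test_benign_side(self):
        ev = aggregate_readout([te(95.0, TranscriptCall.B_S), te(5.0, TranscriptCall.NA)])
        assert (ev.code, ev.points) == ("BP7_O", -4)

    def test_exact_boundaries(self):
        # >= at the 90% share, strict > at the 10% floor
        ev = aggregate_readout([te(90.0, TranscriptCall.P_VS), te(10.0, TranscriptCall.P_P)])
        assert ev.strength is Strength.VERY_STRONG
        ev = aggregate_readout([te(89.9, TranscriptCall.P_VS)])
        assert ev.strength is Strength.NOT_APPLICABLE

    def test_all_below_floor_falls_back_to_weakest(self):
        items = [te(9.0, TranscriptCall.P_VS) for _ in range(10)]
        items.append(te(5.0, TranscriptCall.P_P))
        ev = aggregate_readout(items)
        assert ev.strength is Strength.SUPPORTING
        assert "weakest" in ev.note

    def test_overfull_readout_rejected(self):
        with pytest.raises(InputError):
            aggregate_readout([te(80.0, TranscriptCall.P_VS), te(30.0, TranscriptCall.P_P)])


class TestPm2:
    def test_absent_allele(self):
        ev = pm2_evidence(0, 250394)
        assert (ev.code, ev.points) == ("PM2_P", 1)

    def test_single_allele(self):
        assert pm2_evidence(1, 246102).points == 1

    def test_common_allele(self):
        assert pm2_evidence(1000, 250000).points == 0

    def test_boundary_frequency(self):
        assert pm2_evidence(25, 250000).points == 1  # exactly 0.01%
        assert pm2_evidence(26, 250000).points == 0

    def test_invalid_counts(self):
        with pytest.raises(InputError):
            pm2_evidence(-1, 100)
        with pytest.raises(InputError):
            pm2_evidence(0, 0)


class TestClassify:
    def _ev(self, code, direction, strength, points):
        return EvidenceStrength(code, direction, strength, points)

    def test_lp_band(self):
        v = classify([
            self._ev("PVS1_O", "pathogenic", Strength.VERY_STRONG, 8),
            self._ev("PM2_P", "pathogenic", Strength.SUPPORTING, 1),
        ])
        assert (v.total_points, v.category) == (9, "LP")

    def test_vus_band(self):
        v = classify([
            self._ev("PVS1_O", "pathogenic", Strength.SUPPORTING, 1),
            self._ev("PM2_P", "pathogenic", Strength.SUPPORTING, 1),
        ])
        assert (v.total_points, v.category) == (2, "VUS")

    def test_empty_evidence_is_vus(self):
        v = classify([])
        assert (v.total_points, v.category) == (0, "VUS")

    @pytest.mark.parametrize(
        "points,category",
        [(10, "P"), (12, "P"), (9, "LP"), (6, "LP"), (5, "VUS"), (0, "VUS"),
         (-1, "LB"), (-6, "LB"), (-7, "B"), (-10, "B")],
    )
    def test_bands(self, points, category):
        items = []
        remaining = points
        sign = 1 if points > 0 else -1
        for mag in (8, 4, 2, 1):
            while abs(remaining) >= mag:
                strength = {8: Strength.VERY_STRONG, 4: Strength.STRONG,
                            2: Strength.MODERATE, 1: Strength.SUPPORTING}[mag]
                d = "pathogenic" if sign > 0 else "benign"
                items.append(EvidenceStrength("X_O", d, strength, sign * mag))
                remaining -= sign * mag
        v = classify(items)
        assert (v.total_points, v.category) == (points, category)

    def test_predictive_codes_replaced_by_assay_codes(self):
        v = classify([
            EvidenceStrength("PVS1", "pathogenic", Strength.VERY_STRONG, 8),
            EvidenceStrength("PVS1_O", "pathogenic", Strength.VERY_STRONG, 8),
            EvidenceStrength("PM2_P", "pathogenic", Strength.SUPPORTING, 1),
        ])
        assert v.total_points == 9  # PVS1 dropped, not combined

    def test_predictive_codes_kept_without_assay_code(self):
        v = classify([EvidenceStrength("PP3", "pathogenic", Strength.SUPPORTING, 1)])
        assert v.total_points == 1

    def test_points_strength_consistency_enforced(self):
        with pytest.raises(InputError):
            EvidenceStrength("X", "pathogenic", Strength.STRONG, 3)


class TestFormatting:
    def test_strings(self):
        assert format_evidence(
            EvidenceStrength("PVS1_O", "pathogenic", Strength.VERY_STRONG, 8)
        ) == "PVS1_O_VS (+8)"
        assert format_evidence(
            EvidenceStrength("PM2_P", "pathogenic", Strength.SUPPORTING, 1)
        ) == "PM2_P (+1)"
        assert format_evidence(
            EvidenceStrength("BP7_O", "benign", Strength.STRONG, -4)
        ) == "BP7_O_S (-4)"
        assert format_evidence(
            EvidenceStrength("PVS1_O/BP7_O", "none", Strength.NOT_APPLICABLE, 0)
        ) == "PVS1_O/BP7_O_N/A"


def random_readout(rng, max_items=4):
    n = int(rng.integers(1, max_items + 1))
    raw = rng.dirichlet(np.ones(n)) * float(rng.uniform(50, 100))
    calls = rng.choice(len(TranscriptCall), n)
    members = list(TranscriptCall)
    return [
        te(float(f), members[int(c)], label=f"t{i}")
        for i, (f, c) in enumerate(zip(raw, calls))
    ]


class TestAggregateProperties:
    def test_agrees_with_bruteforce_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(2000):
            items = random_readout(rng)
            got = aggregate_readout(items)
            direction, points = oracle_aggregate(items)
            assert (got.direction, got.points) == (direction, points), items

    def test_permutation_invariance(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            items = random_readout(rng)
            base = aggregate_readout(items)
            perm = list(items)
            rng.shuffle(perm)
            other = aggregate_readout(perm)
            assert (base.code, base.strength, base.points) == (
                other.code, other.strength, other.points,
            )

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_upgrading_pathogenic_never_weakens(self, seed):
        rng = np.random.default_rng(seed)
        items = random_readout(rng)
        path_idx = [
            i for i, it in enumerate(items) if it.call.direction == "pathogenic"
        ]
        if not path_idx:
            return
        i = path_idx[int(rng.integers(len(path_idx)))]
        order = [TranscriptCall.P_P, TranscriptCall.P_M, TranscriptCall.P_S,
                 TranscriptCall.P_VS]
        pos = order.index(items[i].call)
        if pos == len(order) - 1:
            return
        upgraded = list(items)
        upgraded[i] = te(items[i].fraction_percent, order[pos + 1], items[i].label)
        assert aggregate_readout(upgraded).points >= aggregate_readout(items).points

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_adding_benign_never_strengthens(self, seed):
        rng = np.random.default_rng(seed)
        items = random_readout(rng)
        total = sum(it.fraction_percent for it in items)
        if total > 90:
            return
        extra = te(float(rng.uniform(0, 100 - total)), TranscriptCall.B_S, "extra")
        assert aggregate_readout(items + [extra]).points <= aggregate_readout(items).points
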