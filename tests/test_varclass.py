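import random

import pytest

from retrodate.datasets import example_variant_ledger, reading_frame_positions
from retrodate.gene_coords import CodingPosition, Region, parse_coding_label
from retrodate.varclass import (
    AncestralCall,
    FixationCall,
    FixationStatus,
    SitePanel,
    assign_ancestral,
    classify_fixation,
    count_fixed_differences,
    panels_from_frame,
    panels_to_frame,
    reconstruct_parent,
)


def cds(n: int) -> CodingPosition:
    return CodingPosition(Region.CDS, n)


class TestClassifyFixation:
    def test_example_ledger_has_exactly_three_fixed_differences(self):
        parent, retro = example_variant_ledger()
        calls = classify_fixation(parent, retro)
        fixed = [c for c in calls if c.status is FixationStatus.FIXED_DIFFERENCE]
        assert sorted(str(c.position) for c in fixed) == ["*606", "144", "759"]

    def test_shared_invariant(self):
        parent = [SitePanel("parent", cds(5), {"a": "G", "b": "G"})]
        retro = [SitePanel("retro", cds(5), {"a": "G"})]
        (call,) = classify_fixation(parent, retro)
        assert call.status is FixationStatus.SHARED_INVARIANT

    def test_one_sided_site_unresolved(self):
        parent = [SitePanel("parent", cds(9), {"a": "G"})]
        (call,) = classify_fixation(parent, [SitePanel("retro", cds(1), {"a": "A"})])[:1]
        assert call.status is FixationStatus.UNRESOLVED

    def test_simulated_sites_match_counting_oracle(self):
        rng = random.Random(1234)
        parent_panels, retro_panels, expected = [], [], []
        for site in range(1, 501):
            pos = cds(site)
            p_alleles = rng.sample("ACGT", rng.choice([1, 1, 1, 2]))
            r_alleles = rng.sample("ACGT", rng.choice([1, 1, 1, 2]))
            parent_panels.append(
                SitePanel("parent", pos, {f"i{k}": a for k, a in enumerate(p_alleles)})
            )
            retro_panels.append(
                SitePanel("retro", pos, {f"i{k}": a for k, a in enumerate(r_alleles)})
            )
            # independent set-cardinality oracle
            ps, rs = set(p_alleles), set(r_alleles)
            if len(ps) > 1 and len(rs) > 1:
                expected.append(FixationStatus.POLYMORPHIC_IN_BOTH)
            elif len(ps) > 1:
                expected.append(FixationStatus.POLYMORPHIC_IN_PARENT)
            elif len(rs) > 1:
                expected.append(FixationStatus.POLYMORPHIC_IN_RETROCOPY)
            elif ps == rs:
                expected.append(FixationStatus.SHARED_INVARIANT)
            else:
                expected.append(FixationStatus.FIXED_DIFFERENCE)
        calls = classify_fixation(parent_panels, retro_panels)
        assert [c.status for c in calls] == expected

    def test_duplicate_observation_never_changes_calls(self):
        parent, retro = example_variant_ledger()
        before = [c.status for c in classify_fixation(parent, retro)]
        for p in parent:
            first = next(iter(p.observations.values()))
            p.observations["dup"] = first
        after = [c.status for c in classify_fixation(parent, retro)]
        assert before == after

    def test_relabeling_individuals_is_symmetric(self):
        parent, retro = example_variant_ledger()
        before = [c.status for c in classify_fixation(parent, retro)]
        relabeled = [
            SitePanel(p.paralog, p.position,
                      {f"x{k}": a for k, a in enumerate(p.observations.values())})
            for p in parent
        ]
        assert [c.status for c in classify_fixation(relabeled, retro)] == before

    def test_missing_data_ignored(self):
        parent = [SitePanel("parent", cds(2), {"a": "G", "b": "N"})]
        retro = [SitePanel("retro", cds(2), {"a": "A"})]
        (call,) = classify_fixation(parent, retro)
        assert call.status is FixationStatus.FIXED_DIFFERENCE

    def test_empty_panels_rejected(self):
        with pytest.raises(ValueError):
            classify_fixation([], [])

    def test_false_fixation_rare_at_maf_above_0_2(self):
        rng = random.Random(77)
        n_ind, n_sites, false_fixed = 20, 500, 0
        for site in range(1, n_sites + 1):
            freq = rng.uniform(0.2, 0.8)
            obs = {f"i{k}": ("A" if rng.random() < freq else "G") for k in range(n_ind)}
            parent = [SitePanel("parent", cds(site), obs)]
            retro = [SitePanel("retro", cds(site), {f"i{k}": "G" for k in range(n_ind)})]
            (call,) = classify_fixation(parent, retro)
            if call.status is FixationStatus.FIXED_DIFFERENCE:
                false_fixed += 1
        assert false_fixed / n_sites < 0.05

    def test_panel_tsv_roundtrip(self):
        parent, retro = example_variant_ledger()
        frame = panels_to_frame(parent + retro)
        back = panels_from_frame(frame)
        assert len(back) == len(parent) + len(retro)
        assert {(p.paralog, str(p.position)) for p in back} == {
            (p.paralog, str(p.position)) for p in parent + retro
        }
        assert all(
            back[i].observations == (parent + retro)[i].observations
            for i in range(len(back))
        )


class TestAssignAncestral:
    def test_unanimous_outgroups(self):
        call = assign_ancestral(
            cds(246), {"T", "G"}, {"near": "G", "mid": "G", "far": "G"}
        )
        assert call.state == "G"

    def test_split_outgroups_ambiguous(self):
        call = assign_ancestral(cds(5), {"G", "A"}, {"near": "G", "mid": "A"})
        assert call.state == "ambiguous"

    def test_repeat_site_always_ambiguous(self):
        call = assign_ancestral(
            parse_coding_label("*184"), {"repeat:12", "repeat:15"}, {"near": "repeat:13"}
        )
        assert call.state == "ambiguous"

    def test_all_missing_is_unresolved_not_exception(self):
        call = assign_ancestral(cds(5), {"G", "A"}, {"near": None, "mid": "N"})
        assert call.state == "unresolved"


class TestReconstructParent:
    def test_one_site_ancestral_is_primary(self):
        calls = {5: AncestralCall(cds(5), "G", (("og", "G"),))}
        res = reconstruct_parent("ACGTGAC", "ACGTAAC", calls)
        assert res.sequence == "ACGTGAC"
        assert res.n_ambiguous == 0

    def test_identical_references(self):
        res = reconstruct_parent("ACGTACGT", "ACGTACGT", {})
        assert res.sequence == "ACGTACGT"

    def test_ambiguous_site_becomes_n(self):
        res = reconstruct_parent("ACGTGAC", "ACGTAAC", {})
        assert res.sequence == "ACGTNAC"
        assert res.ambiguous_positions == [5]

    def test_indel_discordance_flagged_and_excluded(self):
        res = reconstruct_parent("ACG--TAC", "ACGGTTAC", {})
        assert res.sequence == "ACGTAC"
        assert res.excluded_regions

    def test_simulated_reconstruction_recovers_ancestor(self):
        rng = random.Random(909)
        for _ in range(200):
            ancestor = "".join(rng.choice("ACGT") for _ in range(200))
            sites = rng.sample(range(200), 12)
            primary, alternate = list(ancestor), list(ancestor)
            calls = {}
            for idx, p in enumerate(sites):
                derived = rng.choice([b for b in "ACGT" if b != ancestor[p]])
                (primary if idx % 2 == 0 else alternate)[p] = derived
                calls[p + 1] = AncestralCall(cds(p + 1), ancestor[p], (("og", ancestor[p]),))
            res = reconstruct_parent("".join(primary), "".join(alternate), calls)
            assert res.sequence == ancestor


class TestCountFixedDifferences:
    def test_ledger_full_mask_counts_three(self):
        parent, retro = example_variant_ledger()
        calls = classify_fixation(parent, retro)
        mask = {c.position for c in calls}
        k, L = count_fixed_differences(calls, mask)
        assert k == 3

    def test_ledger_mask_excluding_utr3_tail_counts_two(self):
        parent, retro = example_variant_ledger()
        calls = classify_fixation(parent, retro)
        mask = {c.position for c in calls if str(c.position) != "*606"}
        k, _ = count_fixed_differences(calls, mask)
        assert k == 2

    def test_ledger_reading_frame_mask_counts_two(self):
        parent, retro = example_variant_ledger()
        calls = classify_fixation(parent, retro)
        k, _ = count_fixed_differences(calls, reading_frame_positions())
        assert k == 2

    def test_empty_mask(self):
        parent, retro = example_variant_ledger()
        calls = classify_fixation(parent, retro)
        assert count_fixed_differences(calls, set()) == (0, 0)

    def test_k_monotone_in_mask(self):
        parent, retro = example_variant_ledger()
        calls = classify_fixation(parent, retro)
        positions = sorted((c.position for c in calls), key=lambda p: p.sort_key)
        last_k = 0
        for i in range(len(positions) + 1):
            k, L = count_fixed_differences(calls, set(positions[:i]))
            assert k >= last_k and L == i
            last_k = k


class TestInvariants:
    def test_fixed_difference_requires_monomorphic(self):
        with pytest.raises(ValueError):
            FixationCall(
                cds(1), FixationStatus.FIXED_DIFFERENCE,
                frozenset({"A", "G"}), frozenset({"C"}),
            )

    def test_ancestral_call_basis_consistency(self):
        with pytest.raises(ValueError):
            AncestralCall(cds(1), "G", (("og", "A"),))
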