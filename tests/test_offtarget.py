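"""Off-target enumeration, CFD scoring, and specificity aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from guidecraft.errors import ConfigurationError, ContractError
from guidecraft.fixtures import PlantSpec, plant_sites, random_genome
from guidecraft.offtarget import (
    PenaltyTable,
    cfd_score,
    find_offtargets,
    specificity_score,
)
from guidecraft.pam_models import relaxed_pattern

from conftest import pick_edit
from oracles import brute_cfd, brute_offtargets

SPACER = "GCTAGACGATCAGTACGATC"


def _edits(n):
    return [pick_edit(SPACER, p) for p in (1, 4, 7, 10, 13, 16)[:n]]


@pytest.fixture(scope="module")
def planted(spcas9):
    """60-kb genome with one planted site at each distance 0..6."""
    genome = random_genome(2, [40_000, 20_000], gc=0.45, seed=41)
    spec = PlantSpec(
        spacer=SPACER, pam="TGG",
        positions=[("chr1", 2_000 + 5_000 * i, "+" if i % 2 == 0 else "-")
                   for i in range(7)],
        mismatch_edits=[_edits(i) for i in range(7)],
    )
    genome, truth = plant_sites(genome, spec, seed=42, clean_distance=7)
    return genome, truth


class TestFindOfftargets:
    def test_exact_self_hit(self, spcas9):
        genome = random_genome(1, [10_000], gc=0.45, seed=5)
        genome, truth = plant_sites(
            genome, PlantSpec(SPACER, "AGG", [("chr1", 4_000, "+")]), seed=6)
        hits = find_offtargets(SPACER, genome, spcas9)
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.strand, h.mismatch_count, h.cfd) == (4_000, "+", 0, 1.0)
        assert h.mismatch_detail == ()

    def test_default_bound_reports_distances_zero_to_four(self, planted, spcas9):
        genome, truth = planted
        hits = find_offtargets(SPACER, genome, spcas9)
        got = {(h.record_id, h.start, h.strand): h.mismatch_count for h in hits}
        expected = {(t["record"], t["start"], t["strand"]): t["mismatch_count"]
                    for t in truth if t["mismatch_count"] < 5}
        assert got == expected
        assert {t["mismatch_count"] for t in truth} == set(range(7))

    def test_truth_fields_match_hits(self, planted, spcas9):
        genome, truth = planted
        hits = {(h.record_id, h.start, h.strand): h
                for h in find_offtargets(SPACER, genome, spcas9)}
        for t in truth:
            if t["mismatch_count"] >= 5:
                continue
            h = hits[(t["record"], t["start"], t["strand"])]
            assert h.site_spacer == t["site_spacer"]
            assert h.site_pam == t["site_pam"]
            assert len(h.mismatch_detail) == h.mismatch_count

    def test_bound_one_returns_exact_matches_only(self, planted, spcas9):
        genome, _ = planted
        hits = find_offtargets(SPACER, genome, spcas9, max_diff_exclusive=1)
        assert all(h.mismatch_count == 0 for h in hits)
        assert len(hits) == 1

    def test_hit_sets_are_nested_in_the_bound(self, planted, spcas9):
        genome, _ = planted
        previous = set()
        for bound in range(1, 7):
            hits = {(h.record_id, h.start, h.strand)
                    for h in find_offtargets(SPACER, genome, spcas9, bound)}
            assert previous <= hits
            previous = hits

    def test_exclusion_interval_removes_the_on_target(self, planted, spcas9):
        genome, truth = planted
        on = next(t for t in truth if t["mismatch_count"] == 0)
        hits = find_offtargets(
            SPACER, genome, spcas9,
            exclude=[(on["record"], on["start"], on["end"])])
        assert all(h.mismatch_count > 0 for h in hits)

    def test_sorted_by_mismatch_then_descending_cfd(self, planted, spcas9):
        genome, _ = planted
        hits = find_offtargets(SPACER, genome, spcas9)
        keys = [(h.mismatch_count, -h.cfd) for h in hits]
        assert keys == sorted(keys)

    def test_wrong_guide_length_is_a_contract_error(self, spcas9, small_genome):
        with pytest.raises(ContractError):
            find_offtargets("ACGT", small_genome, spcas9)
        with pytest.raises(ContractError):
            find_offtargets(SPACER, small_genome, spcas9, max_diff_exclusive=0)

    @pytest.mark.parametrize("bound", [1, 2, 3, 4, 5, 6])
    def test_equals_exhaustive_scan_at_every_bound(self, bound, spcas9, small_genome,
                                                   penalty_table):
        """Pigeonhole search equals a window-by-window Hamming scan."""
        rng = np.random.default_rng(bound)
        seq = small_genome["chr1"]
        starts = rng.integers(0, len(seq) - 20, size=8)
        guides = ["".join(seq[s:s + 20]) for s in starts]
        pattern = relaxed_pattern(spcas9.pattern)
        for guide in guides:
            if "N" in guide:
                continue
            got = sorted((h.record_id, h.start, h.strand, h.mismatch_count,
                          h.site_spacer, h.site_pam)
                         for h in find_offtargets(guide, small_genome, spcas9, bound))
            expected = brute_offtargets(guide, small_genome, pattern,
                                        "three_prime", bound)
            assert got == expected

    def test_canonical_only_restricts_pams(self, planted, spcas9):
        genome, _ = planted
        hits = find_offtargets(SPACER, genome, spcas9, canonical_pam_only=True)
        assert all(h.site_pam[1:] == "GG" for h in hits)


class TestCfd:
    def test_perfect_match_canonical_pam_scores_one(self, penalty_table):
        assert cfd_score(SPACER, SPACER, "TGG", penalty_table) == 1.0

    def test_single_mismatch_equals_table_entry(self, penalty_table):
        pos, base = pick_edit(SPACER, 7)
        site = SPACER[:6] + base + SPACER[7:]
        expected = penalty_table.mismatch_penalty[(7, SPACER[6], base)]
        assert cfd_score(SPACER, site, "AGG", penalty_table) == pytest.approx(expected)

    def test_two_mismatches_multiply(self, penalty_table):
        (p1, b1), (p2, b2) = pick_edit(SPACER, 3), pick_edit(SPACER, 15)
        site = list(SPACER)
        site[p1 - 1], site[p2 - 1] = b1, b2
        site = "".join(site)
        expected = (penalty_table.mismatch_penalty[(p1, SPACER[p1 - 1], b1)]
                    * penalty_table.mismatch_penalty[(p2, SPACER[p2 - 1], b2)])
        assert cfd_score(SPACER, site, "CGG", penalty_table) == pytest.approx(expected)

    def test_noncanonical_pam_downweights(self, penalty_table):
        assert cfd_score(SPACER, SPACER, "TAG", penalty_table) \
            == pytest.approx(penalty_table.pam_penalty["NAG"])

    @settings(max_examples=100, deadline=None)
    @given(data=st.data())
    def test_matches_positional_loop_oracle(self, data, penalty_table):
        site = data.draw(st.text(alphabet="ACGT", min_size=20, max_size=20))
        pam = "AGG" if data.draw(st.booleans()) else "TAG"
        got = cfd_score(SPACER, site, pam, penalty_table)
        expected = brute_cfd(SPACER, site, penalty_table.pam(pam),
                             penalty_table.mismatch_penalty)
        assert got == pytest.approx(expected)
        assert 0.0 <= got <= 1.0

    @settings(max_examples=60, deadline=None)
    @given(data=st.data())
    def test_adding_a_mismatch_never_increases_the_score(self, data, penalty_table):
        positions = data.draw(st.lists(st.integers(1, 20), unique=True,
                                       min_size=0, max_size=6))
        site = SPACER
        score = cfd_score(SPACER, site, "GGG", penalty_table)
        for p in positions:
            _, base = pick_edit(site, p)
            site = site[:p - 1] + base + site[p:]
            new = cfd_score(SPACER, site, "GGG", penalty_table)
            assert new <= score + 1e-12
            score = new

    def test_missing_table_entry_names_the_triple(self, penalty_table):
        crippled = PenaltyTable(
            mismatch_penalty={}, pam_penalty=dict(penalty_table.pam_penalty),
            pam_pattern="NGG", source_tag="test")
        pos, base = pick_edit(SPACER, 5)
        site = SPACER[:4] + base + SPACER[5:]
        with pytest.raises(ConfigurationError, match="position 5"):
            cfd_score(SPACER, site, "AGG", crippled)


class TestSpecificity:
    def test_closed_forms(self):
        assert specificity_score([]) == 1.0
        assert specificity_score([1.0]) == 0.5
        assert specificity_score([0.2, 0.3]) == pytest.approx(1 / 1.5)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), max_size=20), st.floats(0.001, 1.0))
    def test_strictly_decreasing_in_any_hit(self, cfds, extra):
        base = specificity_score(cfds)
        assert specificity_score(cfds + [extra]) < base
        assert 0.0 < base <= 1.0
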