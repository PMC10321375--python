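"""Design orchestration: single target, shared guides, batch mode."""

import pytest

from guidecraft._seq import revcomp
from guidecraft.design import DesignParams, batch_design, design_for_sequence, shared_guides
from guidecraft.errors import ContractError, ProvenanceError
from guidecraft.fixtures import PlantSpec, plant_sites, random_genome
from guidecraft.genome_index import build_index
from guidecraft.offtarget import specificity_score
from guidecraft.pam_models import enumerate_protospacers

from conftest import pick_edit


def _embed(background: dict[str, str], insert: str, record: str, offset: int):
    seq = background[record]
    out = dict(background)
    out[record] = seq[:offset] + insert + seq[offset + len(insert):]
    return out


@pytest.fixture(scope="module")
def clean_setup(spcas9):
    """A target embedded exactly once in an otherwise unrelated genome."""
    target = random_genome(1, [300], gc=0.5, seed=81)["chr1"]
    genome = random_genome(2, [15_000, 8_000], gc=0.45, seed=82)
    genome = _embed(genome, target, "chr1", 5_000)
    index = build_index(genome, spcas9)
    return target, genome, index


class TestDesignForSequence:
    def test_clean_target_all_unique_full_specificity(self, clean_setup, spcas9):
        target, genome, index = clean_setup
        reports = design_for_sequence(target, None, index, genome)
        assert reports
        n_cands = len(enumerate_protospacers(target, spcas9))
        assert len(reports) == n_cands
        for r in reports:
            assert r.flags.is_unique
            # the on-target locus is excluded, and the background was drawn
            # independently, so near matches are overwhelmingly unlikely
            assert r.flags.specificity == 1.0
            assert r.hits == []

    def test_duplicated_target_marks_everything_not_unique(self, clean_setup, spcas9):
        target, genome, _ = clean_setup
        dup = _embed(genome, target, "chr2", 2_000)
        index = build_index(dup, spcas9)
        reports = design_for_sequence(target, None, index, dup)
        assert reports
        assert all(not r.flags.is_unique for r in reports)

    def test_planted_two_mismatch_offtarget_hits_one_guide(self, clean_setup, spcas9):
        target, genome, _ = clean_setup
        reports0 = design_for_sequence(target, None, build_index(genome, spcas9), genome)
        chosen = reports0[0].candidate
        edits = [pick_edit(chosen.spacer, 4), pick_edit(chosen.spacer, 12)]
        genome2, truth = plant_sites(
            genome, PlantSpec(chosen.spacer, "TGG", [("chr2", 3_000, "+")], [edits]),
            seed=83, clean_distance=5)
        index2 = build_index(genome2, spcas9)
        reports = design_for_sequence(target, None, index2, genome2)
        by_spacer = {r.candidate.spacer: r for r in reports}
        hit_guide = by_spacer[chosen.spacer]
        assert [(h.mismatch_count, h.start) for h in hit_guide.hits] \
            == [(2, truth[0]["start"])]
        # every guide's hit list equals the brute-force scan minus the
        # on-target locus (the embedded copy of the target on chr1)
        from guidecraft.pam_models import relaxed_pattern
        from oracles import brute_offtargets
        on_target = ("chr1", 5_000, 5_000 + len(target))
        for r in reports:
            expected = [
                (rid, s, st, d)
                for rid, s, st, d, *_ in brute_offtargets(
                    r.candidate.spacer, genome2, relaxed_pattern("NGG"),
                    "three_prime", 5)
                if not (rid == on_target[0]
                        and s < on_target[2] and s + 20 > on_target[1])
            ]
            got = [(h.record_id, h.start, h.strand, h.mismatch_count)
                   for h in r.hits]
            assert sorted(got) == sorted(expected)

    def test_ranking_matches_recomputed_keys(self, clean_setup, spcas9):
        target, genome, index = clean_setup
        reports = design_for_sequence(target, None, index, genome)
        keys = [
            (not r.flags.is_unique, -r.flags.specificity,
             -(r.flags.activity if r.flags.activity is not None else float("-inf")),
             r.candidate.record_id or "", r.candidate.start, r.candidate.strand)
            for r in reports
        ]
        assert keys == sorted(keys)
        assert [r.rank for r in reports] == list(range(1, len(reports) + 1))
        for r in reports:
            assert r.flags.specificity == pytest.approx(specificity_score(r.hits))

    def test_deterministic_across_runs(self, clean_setup):
        target, genome, index = clean_setup
        a = design_for_sequence(target, None, index, genome)
        b = design_for_sequence(target, None, index, genome)
        assert [(r.candidate, r.flags, r.rank) for r in a] \
            == [(r.candidate, r.flags, r.rank) for r in b]

    def test_digest_mismatch_is_a_provenance_error(self, clean_setup, spcas9):
        target, genome, index = clean_setup
        other = random_genome(1, [5_000], gc=0.5, seed=99)
        with pytest.raises(ProvenanceError):
            design_for_sequence(target, None, index, other)

    def test_require_unique_changes_only_order_never_the_set(self, clean_setup, spcas9):
        target, genome, _ = clean_setup
        dup = _embed(genome, target, "chr2", 2_000)
        index = build_index(dup, spcas9)
        strict = design_for_sequence(target, None, index, dup, DesignParams(require_unique=True))
        lax = design_for_sequence(target, None, index, dup, DesignParams(require_unique=False))
        assert {r.candidate.spacer for r in strict} == {r.candidate.spacer for r in lax}


class TestSharedGuides:
    def test_identical_sequences_share_every_candidate(self, clean_setup, spcas9):
        target, genome, index = clean_setup
        shared = shared_guides({"a": target, "b": target}, index, genome)
        expected = {c.spacer for c in enumerate_protospacers(target, spcas9)}
        assert {r.candidate.spacer for r in shared} == expected

    def test_disjoint_sequences_share_nothing(self, clean_setup, spcas9):
        target, genome, index = clean_setup
        other = random_genome(1, [300], gc=0.5, seed=85)["chr1"]
        assert shared_guides({"a": target, "b": other}, index, genome) == []

    def test_engineered_common_cassette_across_three_genes(self, spcas9):
        cassette = "GCTAGACGATCAGTACGATC" + "TGG"
        genes = {}
        for i, seed in enumerate((91, 92, 93)):
            block = random_genome(1, [200], gc=0.5, seed=seed)["chr1"]
            genes[f"g{i}"] = block[:90] + cassette + block[90 + len(cassette):]
        genome = random_genome(1, [10_000], gc=0.45, seed=94)
        for i, g in enumerate(genes.values()):
            genome = _embed(genome, g, "chr1", 1_000 + 2_000 * i)
        index = build_index(genome, spcas9)
        shared = shared_guides(genes, index, genome)

        # brute-force intersection of per-gene candidate spacer sets
        sets = [
            {c.spacer for c in enumerate_protospacers(seq, spcas9)}
            for seq in genes.values()
        ]
        expected = sets[0] & sets[1] & sets[2]
        assert {r.candidate.spacer for r in shared} == expected
        cassette_report = next(r for r in shared
                               if r.candidate.spacer == cassette[:20])
        assert set(cassette_report.occurrences) == set(genes)
        assert all(len(v) == 1 for v in cassette_report.occurrences.values())
        assert cassette_report.flags.is_unique   # genome count == 3 == n targets

    def test_fewer_than_two_targets_rejected(self, clean_setup):
        target, genome, index = clean_setup
        with pytest.raises(ContractError):
            shared_guides({"only": target}, index, genome)


class TestBatchDesign:
    def test_batch_of_one_equals_single_run(self, clean_setup):
        target, genome, index = clean_setup
        single = design_for_sequence(target, None, index, genome, target_id="t1")
        batch = batch_design({"t1": target}, index, genome)
        assert [(r.candidate, r.flags, r.rank) for r in batch["t1"]] \
            == [(r.candidate, r.flags, r.rank) for r in single]

    def test_batch_identical_to_independent_runs(self, spcas9):
        genome = random_genome(1, [20_000], gc=0.45, seed=95)
        index = build_index(genome, spcas9)
        targets = {
            f"t{i}": genome["chr1"][i * 2_000: i * 2_000 + 250] for i in range(4)
        }
        batch = batch_design(targets, index, genome)
        assert list(batch) == list(targets)
        for tid, seq in targets.items():
            solo = design_for_sequence(seq, None, index, genome, target_id=tid)
            assert [(r.candidate, r.flags, r.rank, r.target_id) for r in batch[tid]] \
                == [(r.candidate, r.flags, r.rank, r.target_id) for r in solo]

    def test_duplicate_ids_and_empty_batch_rejected(self, clean_setup):
        target, genome, index = clean_setup
        with pytest.raises(ContractError):
            batch_design([("a", target), ("a", target)], index, genome)
        with pytest.raises(ContractError):
            batch_design({}, index, genome)
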