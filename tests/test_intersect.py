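import math
from fractions import Fraction

import numpy as np
import pytest

from ptmut.intersect import (
    acidic_mutation_scan,
    expected_ptm_mutations,
    find_direct_hits,
    find_flank_hits,
    fisher_enrichment,
    flag_mimics,
)
from ptmut.model import (
    MutationSource,
    PTMSite,
    ProteinRecord,
    Relation,
    ValidationError,
)
from tests.conftest import make_mutation


def phospho(protein="P1", pos=33, res="S"):
    return PTMSite(protein_id=protein, position=pos, residue=res,
                   ptm_type="phosphorylation")


class TestDirectHits:
    def test_phosphosite_destruction(self):
        sites = [phospho(pos=33)]
        muts = [make_mutation(position=33, wt="S", mut="F")]
        (rec,) = find_direct_hits(muts, sites)
        assert rec.relation is Relation.DIRECT_LOSS
        assert rec.offset == 0

    def test_adjacent_position_is_not_direct(self):
        sites = [PTMSite("P1", 120, "K", "acetylation")]
        muts = [make_mutation(position=121, wt="A", mut="T")]
        assert find_direct_hits(muts, sites) == []

    def test_multiply_annotated_residue_fans_out(self):
        sites = [
            PTMSite("P1", 10, "K", "acetylation"),
            PTMSite("P1", 10, "K", "ubiquitylation"),
        ]
        muts = [make_mutation(position=10, wt="K", mut="R")]
        records = find_direct_hits(muts, sites)
        assert len(records) == 2
        assert {r.site.ptm_type for r in records} == {"acetylation", "ubiquitylation"}

    def test_wt_residue_mismatch_raises(self):
        sites = [phospho(pos=33, res="S")]
        muts = [make_mutation(position=33, wt="T", mut="A")]
        with pytest.raises(ValidationError, match="site residue"):
            find_direct_hits(muts, sites)

    def test_source_swap_changes_only_tag(self):
        sites = [phospho(pos=33)]
        somatic = [make_mutation(position=33, wt="S", mut="F",
                                 source=MutationSource.SOMATIC)]
        germline = [make_mutation(position=33, wt="S", mut="F",
                                  source=MutationSource.GERMLINE, sample="rs1")]
        (a,), (b,) = find_direct_hits(somatic, sites), find_direct_hits(germline, sites)
        assert (a.mutation_type, a.site, a.relation, a.offset) == \
               (b.mutation_type, b.site, b.relation, b.offset)
        assert a.source != b.source


class TestMimics:
    @pytest.mark.parametrize(
        "res,pos,mut", [("Y", 62, "D"), ("S", 32, "E"), ("T", 41, "D")]
    )
    def test_acidic_substitution_on_phosphosite_is_mimic(self, res, pos, mut):
        sites = [phospho(pos=pos, res=res)]
        muts = [make_mutation(position=pos, wt=res, mut=mut)]
        (rec,) = flag_mimics(muts, sites)
        assert rec.relation is Relation.MIMIC

    def test_alanine_substitution_is_plain_loss(self):
        sites = [phospho(pos=32, res="S")]
        muts = [make_mutation(position=32, wt="S", mut="A")]
        (rec,) = find_direct_hits(muts, sites)
        assert rec.relation is Relation.DIRECT_LOSS
        assert flag_mimics(muts, sites) == []

    def test_acidic_on_acetyl_lysine_is_never_mimic(self):
        sites = [PTMSite("P1", 10, "K", "acetylation")]
        muts = [make_mutation(position=10, wt="K", mut="E")]
        (rec,) = find_direct_hits(muts, sites)
        assert rec.relation is Relation.DIRECT_LOSS

    def test_mimics_and_losses_partition_coincident_pairs(self):
        sites = [phospho(pos=5, res="S"), phospho(pos=9, res="Y")]
        muts = [
            make_mutation(position=5, wt="S", mut="D"),
            make_mutation(position=9, wt="Y", mut="F"),
        ]
        records = find_direct_hits(muts, sites)
        assert len(records) == 2
        relations = {r.mutation_type: r.relation for r in records}
        assert relations[("P1", 5, "S", "D")] is Relation.MIMIC
        assert relations[("P1", 9, "Y", "F")] is Relation.DIRECT_LOSS


class TestFlankHits:
    def test_offset_plus_four(self):
        sites = [phospho(pos=33)]
        muts = [make_mutation(position=37, wt="S", mut="F")]
        (rec,) = find_flank_hits(muts, sites)
        assert rec.relation is Relation.FLANK and rec.offset == 4

    def test_outside_window_excluded(self):
        sites = [phospho(pos=33)]
        muts = [make_mutation(position=39, wt="A", mut="V")]
        assert find_flank_hits(muts, sites) == []

    def test_offset_zero_excluded(self):
        sites = [phospho(pos=33)]
        muts = [make_mutation(position=33, wt="S", mut="F")]
        assert find_flank_hits(muts, sites) == []

    def test_one_mutation_flanks_two_sites(self):
        sites = [phospho(pos=33), phospho(pos=28)]
        muts = [make_mutation(position=30, wt="A", mut="V")]
        records = find_flank_hits(muts, sites)
        assert sorted(r.offset for r in records) == [-3, 2]

    def test_deterministic_ordering(self):
        sites = [phospho(pos=p) for p in (40, 20, 30)]
        muts = [
            make_mutation(position=p, wt="A", mut="V", sample=f"s{p}")
            for p in (22, 41, 28, 18)
        ]
        records = find_flank_hits(muts, sites)
        keys = [(r.site.protein_id, r.site.position, r.offset) for r in records]
        assert keys == sorted(keys)

    def test_invalid_half_width(self):
        with pytest.raises(ValueError):
            find_flank_hits([], [], half_width=0)


class TestAcidicScan:
    def test_examples(self):
        muts = [
            make_mutation(position=600, wt="V", mut="E"),  # BRAF V600E-like
            make_mutation(position=700, wt="K", mut="E"),  # SF3B1 K700E-like
            make_mutation(position=12, wt="G", mut="V"),
        ]
        hits = acidic_mutation_scan(muts)
        assert [(m.position, m.mut_residue) for m, _ in hits] == [(600, "E"), (700, "E")]

    def test_ptm_annotation_flag(self):
        sites = [phospho(pos=62, res="Y")]
        muts = [
            make_mutation(position=62, wt="Y", mut="D"),
            make_mutation(position=99, wt="A", mut="D"),
        ]
        flags = {m.position: on_site for m, on_site in acidic_mutation_scan(muts, sites)}
        assert flags == {62: True, 99: False}


def fisher_oracle(table):
    """Exhaustive two-tailed hypergeometric sum in exact rational arithmetic."""
    (a, b), (c, d) = table
    N, K, n = a + b + c + d, a + b, a + c

    def pmf(x):
        return Fraction(math.comb(K, x) * math.comb(N - K, n - x), math.comb(N, n))

    p_obs = pmf(a)
    lo, hi = max(0, n - (N - K)), min(K, n)
    return float(sum(pmf(x) for x in range(lo, hi + 1) if pmf(x) <= p_obs))


class TestFisher:
    def test_balanced_table_is_one(self):
        assert fisher_enrichment([[5, 5], [5, 5]]) == pytest.approx(1.0, abs=1e-12)

    def test_diagonal_table(self):
        # 2 / C(20,10), both extreme diagonal tables
        expected = 2 / math.comb(20, 10)
        assert fisher_enrichment([[10, 0], [0, 10]]) == pytest.approx(expected, rel=1e-10)

    def test_two_tailed_symmetry(self):
        assert fisher_enrichment([[0, 10], [10, 0]]) == pytest.approx(
            fisher_enrichment([[10, 0], [0, 10]]), rel=1e-12
        )

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            fisher_enrichment([[1, -1], [2, 3]])

    def test_matches_exhaustive_oracle_on_random_tables(self):
        rng = np.random.default_rng(17)
        for _ in range(300):
            table = [[int(rng.integers(0, 16)) for _ in range(2)] for _ in range(2)]
            if sum(map(sum, table)) == 0:
                continue
            assert fisher_enrichment(table) == pytest.approx(
                fisher_oracle(table), abs=1e-10
            ), table

    def test_agrees_with_scipy_reference(self):
        from scipy.stats import fisher_exact

        rng = np.random.default_rng(23)
        for _ in range(50):
            table = [[int(rng.integers(0, 12)) for _ in range(2)] for _ in range(2)]
            if sum(map(sum, table)) == 0:
                continue
            assert fisher_enrichment(table) == pytest.approx(
                fisher_exact(table, alternative="two-sided")[1], rel=1e-7, abs=1e-12
            )


class TestExpectedCounts:
    def make_proteome(self, sequences):
        return {
            f"P{i+1}": ProteinRecord(f"P{i+1}", seq) for i, seq in enumerate(sequences)
        }

    def test_printed_product_formula(self):
        # 10 S residues, 1 phosphosite => proportion 0.1; 5 mutations on S
        proteome = self.make_proteome(["S" * 10])
        sites = [phospho(pos=1)]
        muts = [
            make_mutation(position=p, wt="S", mut="F", sample=f"s{p}")
            for p in (2, 3, 4, 5, 6)
        ]
        (result,) = expected_ptm_mutations(muts, sites, proteome)
        assert result.expected == pytest.approx(5 * (1 / 10))
        assert result.observed == 0

    def test_integer_rate_case(self):
        # 1000 K residues, 200 acetylated, 60 mutations on K => expected 12
        proteome = self.make_proteome(["K" * 500, "K" * 500])
        sites = [
            PTMSite(pid, pos, "K", "acetylation")
            for pid, positions in (("P1", range(1, 101)), ("P2", range(1, 101)))
            for pos in positions
        ]
        muts = [
            make_mutation("P1", position=400 + i, wt="K", mut="R", sample=f"s{i}")
            for i in range(60)
        ]
        (result,) = expected_ptm_mutations(muts, sites, proteome)
        assert result.expected == pytest.approx(60 * (200 / 1000))
        assert result.expected == pytest.approx(12.0)

    def test_zero_mutations_on_letter(self):
        proteome = self.make_proteome(["YAYA"])
        sites = [phospho(pos=1, res="Y")]
        muts = [make_mutation(position=2, wt="A", mut="V")]
        (result,) = expected_ptm_mutations(muts, sites, proteome)
        assert result.expected == 0.0 and result.observed == 0

    def test_observed_counts_site_landings(self):
        proteome = self.make_proteome(["SSSS"])
        sites = [phospho(pos=1), phospho(pos=2)]
        muts = [
            make_mutation(position=1, wt="S", mut="F", sample="s1"),
            make_mutation(position=3, wt="S", mut="F", sample="s2"),
        ]
        (result,) = expected_ptm_mutations(muts, sites, proteome)
        assert result.observed == 1
        # contingency over residue positions: 1 of 2 site positions mutated,
        # 1 of 2 non-site S positions mutated
        assert result.contingency == ((1, 1), (1, 1))
        assert result.p_value == pytest.approx(1.0)

    def test_absent_letter_skipped_with_warning(self):
        proteome = self.make_proteome(["AAAA"])
        sites = [phospho("P1", 1, "S")]  # S never occurs in the proteome
        with pytest.warns(UserWarning, match="absent"):
            results = expected_ptm_mutations([], sites, proteome)
        assert results == []

    def test_ratio_converges_on_independent_planting(self):
        """With sites and mutations planted independently, observed/expected -> 1."""
        rng = np.random.default_rng(5)
        n = 20000
        seq = "S" * n
        proteome = self.make_proteome([seq])
        site_mask = rng.random(n) < 0.2
        sites = [phospho("P1", i + 1) for i in np.flatnonzero(site_mask)]
        positions = rng.choice(n, size=2000, replace=False)
        muts = [
            make_mutation("P1", position=int(p) + 1, wt="S", mut="F", sample=f"s{j}")
            for j, p in enumerate(positions)
        ]
        (result,) = expected_ptm_mutations(muts, sites, proteome)
        # binomial CI: observed ~ Bin(2000, 0.2) within ~5 sigma of expected
        sigma = math.sqrt(2000 * 0.2 * 0.8)
        assert abs(result.observed - result.expected) < 5 * sigma

    def test_benjamini_hochberg_adjustment_optional(self):
        proteome = self.make_proteome(["SK" * 50])
        sites = [phospho(pos=1), PTMSite("P1", 2, "K", "acetylation")]
        muts = [make_mutation(position=1, wt="S", mut="F")]
        raw = expected_ptm_mutations(muts, sites, proteome)
        assert all(r.adjusted_p is None for r in raw)
        adj = expected_ptm_mutations(muts, sites, proteome, adjust=True)
        assert all(r.adjusted_p is not None for r in adj)
        assert all(r.adjusted_p >= r.p_value - 1e-12 for r in adj)
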