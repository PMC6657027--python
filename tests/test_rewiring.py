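import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ptmut.model import (
    AMINO_ACIDS,
    DeltaScore,
    FlankPair,
    IntersectionRecord,
    MutationSource,
    PTMSite,
    ProteinRecord,
    Relation,
    ValidationError,
)
from ptmut.rewiring import (
    build_flank_pairs,
    calibrate_background,
    delta_score,
    extract_flank,
    pssm_score,
    read_delta_scores,
    sign_agreement,
)
from ptmut.synthetic import MotifSpec, generate_pssm_set
from tests.conftest import uniform_pssm


flank_strategy = st.text(alphabet=AMINO_ACIDS, min_size=15, max_size=15)


def random_pssm(rng, half_width=7):
    pssm = uniform_pssm(0.0, half_width=half_width, name="rand")
    for key in pssm.weights:
        pssm.weights[key] = float(rng.normal(0, 1))
    return pssm


def brute_force_score(flank, pssm):
    """Independent per-position summation oracle."""
    total = 0.0
    for i, ch in enumerate(flank):
        if ch == "X":
            total += pssm.pad_score
        else:
            total += pssm.weights[(i - pssm.half_width, ch)]
    return total


class TestExtractFlank:
    def test_interior_window(self):
        protein = ProteinRecord("P1", "ACDEFGHIKLMNPQRSTVWY")
        assert extract_flank(protein, 8) == "ACDEFGHIKLMNPQR"

    def test_n_terminal_padding(self):
        protein = ProteinRecord("P1", "ACDEFGHIKLMNPQRSTVWY")
        flank = extract_flank(protein, 1)
        assert flank == "XXXXXXX" + "ACDEFGHI"
        assert len(flank) == 15 and flank[7] == "A"

    def test_c_terminal_padding(self):
        protein = ProteinRecord("P1", "ACDEFGHIKLMNPQRSTVWY")
        flank = extract_flank(protein, 20)
        assert flank == "NPQRSTVWY" [-8:] + "XXXXXXX"
        assert len(flank) == 15 and flank[7] == "Y"

    def test_out_of_range(self):
        protein = ProteinRecord("P1", "ACD")
        with pytest.raises(ValidationError):
            extract_flank(protein, 4)


def flank_record(site_pos, mut_pos, wt, mut, protein_id="P1"):
    site = PTMSite(protein_id, site_pos, "S", "phosphorylation")
    return IntersectionRecord(
        mutation_type=(protein_id, mut_pos, wt, mut),
        site=site,
        relation=Relation.FLANK,
        offset=mut_pos - site_pos,
        source=MutationSource.SOMATIC,
    )


class TestBuildFlankPairs:
    def make_proteome(self, seq):
        return {"P1": ProteinRecord("P1", seq)}

    def test_substitution_at_offset_index(self):
        seq = list("A" * 60)
        seq[33 - 1] = "S"
        seq[37 - 1] = "F"
        proteome = self.make_proteome("".join(seq))
        (pair,) = build_flank_pairs([flank_record(33, 37, "F", "W")], proteome)
        assert pair.wt_flank[7] == "S"
        diffs = [i for i in range(15) if pair.wt_flank[i] != pair.mut_flank[i]]
        assert diffs == [7 + 4]
        assert pair.mut_flank[11] == "W"

    def test_negative_offset_index(self):
        seq = list("A" * 60)
        seq[33 - 1] = "S"
        seq[28 - 1] = "R"
        proteome = self.make_proteome("".join(seq))
        (pair,) = build_flank_pairs([flank_record(33, 28, "R", "H")], proteome)
        assert pair.mut_flank[2] == "H" and pair.wt_flank[2] == "R"

    def test_wt_mismatch_raises(self):
        seq = list("A" * 60)
        seq[33 - 1] = "S"
        proteome = self.make_proteome("".join(seq))
        with pytest.raises(ValidationError, match="wild-type"):
            build_flank_pairs([flank_record(33, 37, "R", "H")], proteome)

    def test_non_flank_record_rejected(self):
        site = PTMSite("P1", 33, "S", "phosphorylation")
        rec = IntersectionRecord(("P1", 33, "S", "F"), site, Relation.DIRECT_LOSS, 0,
                                 MutationSource.SOMATIC)
        with pytest.raises(ValidationError, match="flank"):
            build_flank_pairs([rec], {"P1": ProteinRecord("P1", "A" * 60)})


class TestPssmScore:
    def test_all_zero_matrix(self):
        assert pssm_score("A" * 15, uniform_pssm(0.0)) == 0.0

    def test_one_hot_matrix(self):
        pssm = uniform_pssm(0.0)
        pssm.weights[(-3, "R")] = 2.0
        flank = "AAAA" + "R" + "A" * 10
        assert flank[4] == "R"  # offset -3 is index 4
        assert pssm_score(flank, pssm) == 2.0

    def test_fully_padded_flank(self):
        assert pssm_score("X" * 15, uniform_pssm(0.0)) == 0.0

    def test_wrong_length_rejected(self):
        with pytest.raises(ValidationError):
            pssm_score("AAA", uniform_pssm(0.0))

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(29)
        letters = list(AMINO_ACIDS) + ["X"]
        for _ in range(200):
            pssm = random_pssm(rng)
            flank = "".join(rng.choice(letters, size=15))
            assert pssm_score(flank, pssm) == pytest.approx(
                brute_force_score(flank, pssm), abs=1e-12
            )


def make_pair(wt_flank, mut_flank):
    site = PTMSite("P1", 100, wt_flank[7] if wt_flank[7] in "STY" else "S",
                   "phosphorylation")
    idx = next(i for i in range(15) if wt_flank[i] != mut_flank[i])
    return FlankPair(
        site=site,
        mutation_type=("P1", 100 + idx - 7, wt_flank[idx], mut_flank[idx]),
        wt_flank=wt_flank,
        mut_flank=mut_flank,
    )


class TestDeltaScore:
    def test_akt_like_arginine_loss(self):
        """R->H at -3 of a basophilic motif predicts loss (delta < 0)."""
        pssm = uniform_pssm(0.0, name="AKT1like", group="basophilic")
        pssm.weights[(-3, "R")] = 3.0
        wt = "AAAA" + "R" + "AA" + "S" + "A" * 7
        mut = wt[:4] + "H" + wt[5:]
        ds = delta_score(make_pair(wt, mut), pssm)
        assert ds.delta == pssm.weights[(-3, "H")] - pssm.weights[(-3, "R")]
        assert ds.delta < 0

    @settings(max_examples=200, deadline=None)
    @given(flank_strategy, st.integers(0, 14), st.sampled_from(AMINO_ACIDS),
           st.integers(0, 2**31 - 1))
    def test_antisymmetry_under_swap(self, wt_flank, idx, new_res, seed):
        if idx == 7 or wt_flank[idx] == new_res:
            return
        mut_flank = wt_flank[:idx] + new_res + wt_flank[idx + 1:]
        pssm = random_pssm(np.random.default_rng(seed))
        forward = delta_score(make_pair(wt_flank, mut_flank), pssm)
        backward = delta_score(make_pair(mut_flank, wt_flank), pssm)
        assert forward.delta == pytest.approx(-backward.delta, abs=1e-12)

    def test_invariant_to_unmutated_offsets(self):
        """Adding a constant column at a non-mutated offset leaves delta fixed."""
        rng = np.random.default_rng(31)
        wt = "AAAA" + "R" + "AA" + "S" + "A" * 7
        mut = wt[:4] + "H" + wt[5:]
        pair = make_pair(wt, mut)
        pssm = random_pssm(rng)
        base = delta_score(pair, pssm).delta
        for off in range(-7, 8):
            if off == -3:
                continue
            perturbed = random_pssm(rng)
            perturbed.weights = dict(pssm.weights)
            for aa in AMINO_ACIDS:
                perturbed.weights[(off, aa)] += 5.0
            assert delta_score(pair, perturbed).delta == pytest.approx(base, abs=1e-12)


class TestCalibrateBackground:
    def make_proteome(self, n=10, length=40, seed=37):
        rng = np.random.default_rng(seed)
        letters = list(AMINO_ACIDS)
        return {
            f"P{i}": ProteinRecord(f"P{i}", "".join(rng.choice(letters, size=length)))
            for i in range(n)
        }

    def test_extremes_and_median(self):
        proteome = self.make_proteome()
        pssm = random_pssm(np.random.default_rng(41))
        percentile = calibrate_background(pssm, proteome)
        scores = sorted(
            pssm_score(extract_flank(p, pos), pssm)
            for p in proteome.values()
            for pos in range(1, len(p.sequence) + 1)
            if p.sequence[pos - 1] in "STY"
        )
        assert len(scores) > 0
        assert percentile(scores[-1]) == 100.0
        assert percentile(scores[0] - 1.0) == 0.0
        median = scores[len(scores) // 2]
        assert percentile(median) == pytest.approx(50.0, abs=100.0 / len(scores) + 1.0)

    def test_no_eligible_residues(self):
        proteome = {"P1": ProteinRecord("P1", "AAAA")}
        with pytest.raises(ValidationError):
            calibrate_background(uniform_pssm(0.0), proteome)


def ds(key_pos, delta, kinase="K1", group="g"):
    return DeltaScore(
        site_protein="P1", site_position=key_pos, mutation_type=("P1", key_pos + 2, "A", "V"),
        kinase_name=kinase, kinase_group=group, wt_score=0.0, mut_score=delta, delta=delta,
    )


class TestSignAgreement:
    def test_enumeration(self):
        a = [ds(1, +1), ds(2, -1), ds(3, +1)]
        b = [ds(1, +2), ds(2, -3), ds(3, -1)]
        report = sign_agreement(a, b)
        assert (report.n_matched, report.n_agree) == (3, 2)
        assert report.fraction_agree == pytest.approx(2 / 3)

    def test_disjoint_keys(self):
        report = sign_agreement([ds(1, 1)], [ds(2, 1)])
        assert report.n_matched == 0 and report.fraction_agree is None

    def test_identical_lists(self):
        a = [ds(i, (-1) ** i * (i + 1)) for i in range(5)]
        report = sign_agreement(a, a)
        assert report.fraction_agree == 1.0

    def test_zero_deltas_excluded_and_counted(self):
        a = [ds(1, 0.0), ds(2, 1.0)]
        b = [ds(1, 5.0), ds(2, 2.0)]
        report = sign_agreement(a, b)
        assert report.n_zero_excluded == 1
        assert (report.n_matched, report.n_agree) == (1, 1)

    def test_symmetry(self):
        rng = np.random.default_rng(43)
        a = [ds(i, float(rng.normal())) for i in range(20)]
        b = [ds(i, float(rng.normal())) for i in range(20)]
        ra, rb = sign_agreement(a, b), sign_agreement(b, a)
        assert (ra.n_matched, ra.n_agree) == (rb.n_matched, rb.n_agree)

    def test_duplicate_keys_rejected(self):
        with pytest.raises(ValidationError):
            sign_agreement([ds(1, 1), ds(1, 2)], [ds(1, 1)])

    def test_per_group_breakdown(self):
        a = [ds(1, 1, "K1", "basophilic"), ds(2, -1, "K2", "proline-directed")]
        b = [ds(1, 1, "K1", "basophilic"), ds(2, 1, "K2", "proline-directed")]
        report = sign_agreement(a, b)
        assert report.per_group == {"basophilic": (1, 1), "proline-directed": (1, 0)}


def test_external_score_orientation_flip(tmp_path):
    from ptmut.rewiring import delta_scores_to_frame

    scores = [ds(1, 1.5), ds(2, -0.5)]
    path = tmp_path / "ext.tsv"
    delta_scores_to_frame(scores).to_csv(path, sep="\t", index=False)
    same = read_delta_scores(path, score_orientation=1)
    flipped = read_delta_scores(path, score_orientation=-1)
    assert [s.delta for s in same] == [1.5, -0.5]
    assert [s.delta for s in flipped] == [-1.5, 0.5]


def test_planted_motif_recovery():
    """All planted R->H events at -3 lose the basophilic motif; H->R gains it."""
    (akt,) = generate_pssm_set(
        7, [MotifSpec("AKT1like", "basophilic", ((-3, "R", 3.0),), noise_sd=0.1)]
    )
    rng = np.random.default_rng(47)
    letters = list(AMINO_ACIDS)
    for _ in range(50):
        flank = list(rng.choice(letters, size=15))
        flank[7] = "S"
        flank[4] = "R"
        wt = "".join(flank)
        mut = wt[:4] + "H" + wt[5:]
        loss = delta_score(make_pair(wt, mut), akt)
        gain = delta_score(make_pair(mut, wt), akt)
        assert loss.delta < 0
        assert gain.delta > 0
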