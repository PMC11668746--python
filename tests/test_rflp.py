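"""In-silico PCR, restriction digestion and fragment-pattern genotyping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from foundertrace.rflp import (
    HPY188III,
    Genotype,
    NoAmplificationError,
    NonSpecificAmplificationError,
    PrimerPair,
    RestrictionEnzyme,
    digest,
    find_sites,
    genotype_from_fragments,
    revcomp,
    simulate_pcr,
)
from foundertrace.simulate import (
    ASSAY_PRIMERS,
    make_nonspecific_template,
    make_rflp_fixture,
)

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def naive_find_sites(seq: str, enzyme: RestrictionEnzyme) -> list[int]:
    """Position-by-position degenerate matcher (independent oracle)."""
    rec = enzyme.recognition
    patterns = [(rec, enzyme.cut_offset)]
    if revcomp(rec) != rec:
        patterns.append((revcomp(rec), len(rec) - enzyme.cut_offset))
    cuts = set()
    for pat, off in patterns:
        for i in range(len(seq) - len(pat) + 1):
            if all(seq[i + j] in _IUPAC[pat[j]] for j in range(len(pat))):
                cuts.add(i + off)
    return sorted(cuts)


dna = st.text(alphabet="ACGT", min_size=0, max_size=300)


class TestFindSites:
    def test_no_match(self):
        assert find_sites("AAAA", HPY188III) == []

    def test_single_exact_site(self):
        assert find_sites("TCGGGA", HPY188III) == [2]

    def test_hpy188iii_is_self_complementary(self):
        assert HPY188III.is_self_complementary

    def test_oracle_equivalence_random_sequences(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            seq = "".join(rng.choice(list("ACGT"), size=rng.integers(50, 1000)))
            assert find_sites(seq, HPY188III) == naive_find_sites(seq, HPY188III)
        # one long sequence as in a plasmid-scale scan
        seq = "".join(rng.choice(list("ACGT"), size=10_000))
        assert find_sites(seq, HPY188III) == naive_find_sites(seq, HPY188III)

    def test_non_self_complementary_scans_both_strands(self):
        enz = RestrictionEnzyme("toy", "GACGT", 1)
        assert not enz.is_self_complementary
        seq = "AAGACGTAA"          # top-strand site at 2
        seq_rc = revcomp(seq)       # bottom-strand site only
        assert find_sites(seq, enz) == naive_find_sites(seq, enz)
        assert find_sites(seq_rc, enz) == naive_find_sites(seq_rc, enz)
        assert find_sites(seq_rc, enz) != []


class TestDigest:
    def test_fixture_wild_type_pattern(self, rflp_fixture):
        _, _, wt, _ = rflp_fixture
        assert sorted(digest(wt, HPY188III).fragment_lengths) == [168, 189]

    def test_fixture_mutant_pattern(self, rflp_fixture):
        _, _, _, mut = rflp_fixture
        assert sorted(digest(mut, HPY188III).fragment_lengths) == [67, 122, 168]

    def test_no_site_returns_whole_molecule(self):
        seq = "A" * 123
        res = digest(seq, HPY188III)
        assert res.fragment_lengths == (123,) and res.n_sites == 0

    @settings(deadline=None, max_examples=80, derandomize=True)
    @given(seq=st.text(alphabet="ACGT", min_size=1, max_size=300))
    def test_fragment_conservation(self, seq):
        res = digest(seq, HPY188III)
        assert sum(res.fragment_lengths) == len(seq)
        assert len(res.fragment_lengths) == res.n_sites + 1

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(seq=st.text(alphabet="ACGT", min_size=1, max_size=300))
    def test_reverse_complement_reverses_fragments(self, seq):
        fwd = digest(seq, HPY188III).fragment_lengths
        rev = digest(revcomp(seq), HPY188III).fragment_lengths
        assert rev == fwd[::-1]


class TestSimulatePcr:
    def test_constructed_template_amplicon_length(self):
        p = ASSAY_PRIMERS
        template = p.forward + "ACGT" * 10 + revcomp(p.reverse)
        amplicon = simulate_pcr(template, p)
        assert len(amplicon) == 22 + 40 + 24 == 86
        assert amplicon == template

    def test_amplicon_from_embedded_template(self, rflp_fixture):
        template, primers, wt, _ = rflp_fixture
        assert simulate_pcr(template, primers) == wt
        assert len(wt) == 357

    def test_missing_reverse_site_fails(self):
        p = ASSAY_PRIMERS
        with pytest.raises(NoAmplificationError):
            simulate_pcr(p.forward + "ACGT" * 20, p)

    def test_duplicated_target_is_nonspecific(self):
        template = make_nonspecific_template(seed=11)
        with pytest.raises(NonSpecificAmplificationError) as exc:
            simulate_pcr(template, ASSAY_PRIMERS)
        assert len(exc.value.products) > 1


class TestGenotypeFromFragments:
    WT = [189, 168]
    MUT = [168, 122, 67]

    @pytest.mark.parametrize(
        "observed, expected",
        [
            ([189, 168], Genotype.WT_WT),
            ([168, 122, 67], Genotype.MUT_MUT),
            ([189, 168, 122, 67], Genotype.WT_MUT),  # shared 168 appears once
            ([500], Genotype.UNCALLED),
            ([189], Genotype.UNCALLED),  # partial pattern
        ],
    )
    def test_gel_lane_calls(self, observed, expected):
        assert genotype_from_fragments(observed, self.WT, self.MUT, 2) == expected

    def test_comigration_tolerance(self):
        assert (
            genotype_from_fragments([190, 167], self.WT, self.MUT, tolerance_bp=2)
            == Genotype.WT_WT
        )
        assert (
            genotype_from_fragments([190, 167], self.WT, self.MUT, tolerance_bp=0)
            == Genotype.UNCALLED
        )

    def test_identical_patterns_rejected(self):
        with pytest.raises(ValueError):
            genotype_from_fragments([1], [5, 6], [6, 5], 0)

    def test_digest_to_call_roundtrip(self, rflp_fixture):
        _, _, wt, mut = rflp_fixture
        wt_frag = digest(wt, HPY188III).fragment_lengths
        mut_frag = digest(mut, HPY188III).fragment_lengths
        het = sorted(set(wt_frag) | set(mut_frag))
        assert genotype_from_fragments(wt_frag, wt_frag, mut_frag) == Genotype.WT_WT
        assert genotype_from_fragments(mut_frag, wt_frag, mut_frag) == Genotype.MUT_MUT
        assert genotype_from_fragments(het, wt_frag, mut_frag) == Genotype.WT_MUT
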