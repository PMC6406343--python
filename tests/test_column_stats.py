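"""Per-column entropy and Simpson diversity: oracles and invariants.

The naive per-column reference implementations below are written directly
from the defining formulas (plain dict counting, ``math.log``) and share no
code with the package path they check.
"""

import math
import random
from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msacompress import (
    Alignment,
    ResidueClassScheme,
    column_entropy,
    column_pdi,
    profile,
)
from msacompress.records import STANDARD_AA

AAS = sorted(STANDARD_AA)


# --- independent reference implementations ---------------------------------

def naive_entropy(column, base=20.0, count_gaps=False):
    counts = Counter(
        c for c in column.upper()
        if c in STANDARD_AA or (count_gaps and c == "-")
    )
    n = sum(counts.values())
    if n == 0:
        return math.nan
    return -sum((c / n) * math.log(c / n, base) for c in counts.values())


def naive_pdi(column, scheme):
    members = {res: name for name, residues in scheme.classes for res in residues}
    counts = Counter(members[c] for c in column.upper() if c in members)
    N = sum(counts.values())
    if N < 2:
        return math.nan
    return 1.0 - sum(n * (n - 1) for n in counts.values()) / (N * (N - 1))


# --- entropy ----------------------------------------------------------------

class TestColumnEntropy:
    def test_fully_conserved_column_is_exactly_zero(self):
        assert column_entropy("AAAA", "20") == 0.0
        assert column_entropy("AAAA", "natural") == 0.0

    def test_uniform_column_base20_is_one(self):
        col = "".join(AAS)
        assert column_entropy(col, "20") == pytest.approx(1.0, abs=1e-12)

    def test_half_quarter_quarter_hand_value(self):
        expect = -(0.5 * math.log(0.5) + 2 * 0.25 * math.log(0.25)) / math.log(20)
        assert column_entropy("AAVF", "20") == pytest.approx(expect, abs=1e-12)
        assert column_entropy("AAVF", "20") == pytest.approx(0.3471, abs=1e-4)

    def test_base_relation(self):
        col = "AAVFWWK"
        assert column_entropy(col, "20") == pytest.approx(
            column_entropy(col, "natural") / math.log(20), abs=1e-12
        )

    def test_all_gap_column_is_missing(self):
        assert math.isnan(column_entropy("----"))

    def test_gap_modes(self):
        # exclude: gaps drop out, leaving a conserved column
        assert column_entropy("AA--", "20", "exclude") == 0.0
        # as_symbol: the gap is a 21st symbol and creates variability
        assert column_entropy("AA--", "20", "as_symbol") == pytest.approx(
            naive_entropy("AA--", 20.0, count_gaps=True)
        )

    def test_ambiguity_codes_excluded(self):
        assert column_entropy("AAXX") == 0.0

    @given(st.lists(st.sampled_from(AAS), min_size=1, max_size=60))
    @settings(max_examples=200, derandomize=True)
    def test_row_permutation_invariance(self, residues):
        col = "".join(residues)
        shuffled = "".join(random.Random(0).sample(col, len(col)))
        assert column_entropy(col) == pytest.approx(column_entropy(shuffled), abs=1e-12)

    @given(st.lists(st.sampled_from(AAS), min_size=1, max_size=60),
           st.randoms(use_true_random=False))
    @settings(max_examples=200, derandomize=True)
    def test_residue_relabeling_invariance(self, residues, rnd):
        # entropy depends only on the count multiset, not residue identity
        col = "".join(residues)
        perm = dict(zip(AAS, rnd.sample(AAS, 20)))
        relabeled = "".join(perm[c] for c in col)
        assert column_entropy(col) == pytest.approx(column_entropy(relabeled), abs=1e-12)


# --- Simpson PDI ------------------------------------------------------------

class TestColumnPDI:
    scheme = ResidueClassScheme.default()

    def test_single_class_column_is_zero(self):
        assert column_pdi("AILV", self.scheme) == 0.0

    def test_two_plus_two_classes(self):
        assert column_pdi("AAFF", self.scheme) == pytest.approx(1 - 4 / 12, abs=1e-12)

    def test_all_singleton_classes(self):
        assert column_pdi("AFGC", self.scheme) == 1.0

    def test_short_column_is_missing(self):
        assert math.isnan(column_pdi("A", self.scheme))
        assert math.isnan(column_pdi("A---", self.scheme))

    def test_within_class_substitution_invariance(self):
        # swapping residues inside one class leaves class counts unchanged
        assert column_pdi("AAFF", self.scheme) == column_pdi("ILYW", self.scheme)
        assert column_pdi("NQST", self.scheme) == column_pdi("SSSS", self.scheme)

    @given(st.lists(st.sampled_from(AAS), min_size=2, max_size=60))
    @settings(max_examples=300, derandomize=True)
    def test_bounded_in_unit_interval(self, residues):
        v = column_pdi("".join(residues), self.scheme)
        assert 0.0 <= v <= 1.0

    @given(st.lists(st.sampled_from(AAS), min_size=2, max_size=40),
           st.integers(0, 7), st.integers(0, 7))
    @settings(max_examples=300, derandomize=True)
    def test_merging_classes_never_increases_pdi(self, residues, i, j):
        col = "".join(residues)
        coarse = ResidueClassScheme.merged(self.scheme, i, j)
        assert column_pdi(col, coarse) <= column_pdi(col, self.scheme) + 1e-12


def test_default_scheme_is_the_eight_type_partition():
    scheme = ResidueClassScheme.default()
    assert scheme.k == 8
    names = [n for n, _ in scheme.classes]
    assert names[:2] == ["hydrophobic", "aromatic"]
    assert dict(scheme.classes)["negative"] == frozenset("DE")
    assert dict(scheme.classes)["positive"] == frozenset("RK")


def test_scheme_must_partition_the_alphabet():
    with pytest.raises(ValueError):
        ResidueClassScheme((("a", frozenset("AILV")),))  # incomplete
    with pytest.raises(ValueError):
        ResidueClassScheme(
            (("a", frozenset("AILV")), ("b", frozenset("VFYW")))  # overlap
        )


def test_scheme_file_round_trip(tmp_path):
    path = tmp_path / "classes.txt"
    path.write_text(
        "# two-class toy scheme\nhydro: AILVFYWGCMP\npolar: NQSTDERKH\n"
    )
    scheme = ResidueClassScheme.from_file(path)
    assert scheme.k == 2
    assert column_pdi("AILV", scheme) == 0.0


# --- whole-alignment profile ------------------------------------------------

class TestProfile:
    def test_identical_sequences_give_zero_profile(self):
        aln = Alignment([(f"s{i}", "MKWDE") for i in range(3)])
        prof = profile(aln)
        assert prof.entropy == [0.0] * 5
        assert prof.pdi == [0.0] * 5

    def test_length_contract_and_gap_fraction(self):
        aln = Alignment([("a", "MK-DE"), ("b", "MKW-E"), ("c", "MKWDE")])
        prof = profile(aln)
        assert len(prof) == 5
        assert prof.gap_fraction == [0.0, 0.0, 1 / 3, 1 / 3, 0.0]
        assert prof.n_effective == [3, 3, 2, 2, 3]

    def test_matches_naive_per_column_loop(self):
        rng = random.Random(7)
        scheme = ResidueClassScheme.default()
        alphabet = AAS + ["-"]
        for _ in range(20):
            n, L = rng.randint(2, 12), rng.randint(1, 30)
            rows = [(f"s{i}", "".join(rng.choice(alphabet) for _ in range(L)))
                    for i in range(n)]
            aln = Alignment(rows)
            prof = profile(aln)
            for j in range(L):
                col = "".join(seq[j] for _, seq in rows)
                assert prof.entropy[j] == pytest.approx(
                    naive_entropy(col), abs=1e-12, nan_ok=True
                )
                assert prof.pdi[j] == pytest.approx(
                    naive_pdi(col, scheme), abs=1e-12, nan_ok=True
                )

    def test_profile_tsv_round_trip(self, tmp_path):
        aln = Alignment([("a", "MK-DE"), ("b", "MKWLE")])
        prof = profile(aln)
        prof.to_tsv(tmp_path / "p.tsv")
        from msacompress import ConservationProfile

        back = ConservationProfile.from_tsv(tmp_path / "p.tsv")
        assert back.entropy == pytest.approx(prof.entropy, abs=1e-9, nan_ok=True)
        assert back.n_effective == prof.n_effective


def test_alignment_validation():
    with pytest.raises(ValueError):
        Alignment([("a", "MK"), ("b", "MKV")])
    with pytest.raises(ValueError):
        Alignment([])


def test_alignment_fasta_and_clustal_readers(tmp_path):
    fa = tmp_path / "aln.fasta"
    fa.write_text(">a\nMK-DE\n>b\nMKWLE\n")
    aln = Alignment.read(fa)
    assert aln.n_rows == 2 and aln.length == 5

    clw = tmp_path / "aln.aln"
    clw.write_text(
        "CLUSTAL W (1.83) multiple sequence alignment\n\n\n"
        "a    MK-DE\nb    MKWLE\n"
    )
    aln2 = Alignment.read(clw)
    assert aln2.rows == aln.rows
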