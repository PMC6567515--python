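import numpy as np
import pytest

from phyloforge.distances import (
    distance_matrix,
    exclude_divergent,
    p_distance,
    select_best_per_taxon,
)
from conftest import mkaln, mkseq


class TestPDistance:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("ACDE", "ACDF", 0.25),  # 1 mismatch / 4 comparable
            ("AC-E", "ACDE", 0.0),  # gap column excluded, 3 comparable
            ("AAAA----", "----CCCC", 1.0),  # no comparable columns -> maximal
            ("AXDE", "AADE", 0.0),  # X columns excluded from both counts
        ],
    )
    def test_examples(self, a, b, expected):
        assert p_distance(mkseq("A", "A@1", a), mkseq("B", "B@1", b)) == expected

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            p_distance(mkseq("A", "A@1", "AA"), mkseq("B", "B@1", "AAA"))

    def test_matrix_matches_scalar_and_is_premetric(self, rng):
        rows = {
            f"t{i}@s": "".join(rng.choice(list("ACDE-X"), 40)) for i in range(6)
        }
        aln = mkaln("g", rows)
        dm = distance_matrix(aln)
        assert np.allclose(dm.d, dm.d.T) and np.all(np.diag(dm.d) == 0)
        for i, a in enumerate(aln.members):
            for j, b in enumerate(aln.members):
                if i < j:
                    assert dm.d[i, j] == pytest.approx(p_distance(a, b))


class TestExcludeDivergent:
    def test_random_contaminant_removed(self, rng):
        # a clean clade of similar sequences plus one planted random sequence:
        # its distance to everything is ~0.95, far over any sane threshold
        base = rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 100)
        rows = {}
        for i in range(5):
            seq = base.copy()
            flip = rng.choice(100, size=5, replace=False)
            seq[flip] = "W"
            rows[f"t{i}@s"] = "".join(seq)
        rows["t5@bad"] = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 100))
        aln = mkaln("g", rows)
        out, removed = exclude_divergent(aln, 0.25)
        assert [r.seq_id for r in removed] == ["t5@bad"]
        assert len(out.members) == 5

    def test_clean_clade_unchanged(self, rng):
        base = rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 100)
        rows = {}
        for i in range(5):
            seq = base.copy()
            flip = rng.choice(100, size=8, replace=False)
            seq[flip] = "W"
            rows[f"t{i}@s"] = "".join(seq)
        out, removed = exclude_divergent(mkaln("g", rows), 0.25)
        assert not removed and len(out.members) == 5

    def test_threshold_one_never_removes(self, rng):
        rows = {f"t{i}@s": "".join(rng.choice(list("ACDE"), 30)) for i in range(4)}
        out, removed = exclude_divergent(mkaln("g", rows), 1.0)
        assert not removed

    def test_single_taxon_gene_unchanged(self):
        aln = mkaln("g", {"A@1": "ACDE", "A@2": "WWWW"})
        out, removed = exclude_divergent(aln, 0.25)
        assert len(out.members) == 2 and not removed


class TestSelectBestPerTaxon:
    def test_hand_computed_toy(self):
        # d(A1,B)=0, d(A1,C)=0.1 -> mean 0.05; d(A2,B)=0.2, d(A2,C)=0.3 -> 0.25
        aln = mkaln(
            "g",
            {
                "A@1": "AAAAAAAAAA",
                "A@2": "CCAAAAAAAA",
                "B@1": "AAAAAAAAAA",
                "C@1": "AAAAAAAAAC",
            },
        )
        out, removed = select_best_per_taxon(aln)
        assert {s.seq_id for s in out.members} == {"A@1", "B@1", "C@1"}
        assert removed[0].seq_id == "A@2"

    def test_equal_means_longer_kept(self):
        aln = mkaln(
            "g",
            {
                "A@long": "AAAAAAAA--",
                "A@short": "AAAAAA----",
                "B@1": "AAAAAAAAAA",
            },
        )
        out, _ = select_best_per_taxon(aln)
        assert "A@long" in {s.seq_id for s in out.members}

    def test_all_single_copy_identity(self):
        aln = mkaln("g", {"A@1": "ACDE", "B@1": "ACDF", "C@1": "ACDA"})
        out, removed = select_best_per_taxon(aln)
        assert out.members == aln.members and not removed

    def test_one_per_taxon_postcondition(self, rng):
        rows = {}
        for i in range(4):
            for j in range(int(rng.integers(1, 4))):
                rows[f"t{i}@s{j}"] = "".join(rng.choice(list("ACDE"), 30))
        out, removed = select_best_per_taxon(mkaln("g", rows))
        taxa = [s.taxon for s in out.members]
        assert len(taxa) == len(set(taxa)) == 4
        assert len(out.members) + len(removed) == len(rows)
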