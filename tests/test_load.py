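"""Consequence annotation, Grantham classes, polarization and R_A/B."""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest

import deerload as dl
from deerload.load import SiteAnnotation
from conftest import make_gm
from oracles import consequence_oracle

DATA = Path(__file__).parent / "data"


class TestGrantham:
    def test_matches_published_matrix(self):
        """All 190 pairs agree exactly with the committed distance table."""
        tab = pd.read_csv(DATA / "grantham_1974_distances.tsv", sep="\t")
        assert len(tab) == 190
        for row in tab.itertuples(index=False):
            assert dl.grantham(row.aa1, row.aa2) == row.distance
            assert dl.grantham(row.aa2, row.aa1) == row.distance

    def test_formula_reproduces_table_within_rounding(self):
        """The composition/polarity/volume formula agrees within +-1."""
        tab = pd.read_csv(DATA / "grantham_1974_distances.tsv", sep="\t")
        diffs = [
            abs(dl.grantham_from_properties(r.aa1, r.aa2) - r.distance)
            for r in tab.itertuples(index=False)
        ]
        assert max(diffs) <= 1

    @pytest.mark.parametrize("pair,score", [(("L", "I"), 5), (("W", "C"), 215)])
    def test_landmarks(self, pair, score):
        assert dl.grantham(*pair) == score

    def test_identity_zero(self):
        for aa in "ACDEFGHIKLMNPQRSTVWY":
            assert dl.grantham(aa, aa) == 0

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValueError):
            dl.grantham("B", "A")


class TestClassify:
    @pytest.mark.parametrize(
        "cons,score,expected",
        [
            ("missense_variant", 155, "missense_deleterious"),
            ("missense_variant", 5, "missense_benign"),
            ("missense_variant", 150, "missense_benign"),  # boundary
            ("splice_acceptor_variant", None, "lof"),
            ("stop_gained", None, "lof"),
            ("stop_retained_variant", None, "lof"),
            ("synonymous_variant", None, "synonymous"),
            ("non_coding", None, "other"),
        ],
    )
    def test_mapping(self, cons, score, expected):
        ann = SiteAnnotation("chr1", 1, cons, grantham=score)
        assert dl.classify(ann) == expected

    def test_stop_retained_reassignment_flag(self):
        ann = SiteAnnotation("chr1", 1, "stop_retained_variant")
        assert dl.classify(ann, stop_retained_is_lof=False) == "synonymous"


@pytest.fixture(scope="module")
def genome():
    return dl.generate_toy_genome(n_genes=4, cds_len=120, seed=7, n_exons=3)


class TestAnnotate:
    def _annotate_one(self, genome, chrom, pos, alt):
        ref = genome.sequences[chrom][pos - 1]
        sites = pd.DataFrame(
            {"chrom": [chrom], "pos": [pos], "ref": [ref], "alt": [alt]}
        )
        return dl.annotate_consequences(sites, genome.sequences, genome.transcripts)[0]

    def test_stop_gained_plus_strand(self, genome):
        """Find a plus-strand site whose substitution creates a stop codon."""
        t = next(t for t in genome.transcripts if t.strand == "+")
        cds = t.cds_sequence(genome.sequences)
        found = None
        for ci in range(3, t.cds_length - 3):
            codon_i, off = divmod(ci, 3)
            codon = cds[3 * codon_i : 3 * codon_i + 3]
            for alt in "ACGT":
                mut = codon[:off] + alt + codon[off + 1 :]
                if mut in ("TAA", "TAG", "TGA") and codon not in ("TAA", "TAG", "TGA") and alt != codon[off]:
                    found = (ci, alt)
                    break
            if found:
                break
        assert found is not None
        ci, alt = found
        # genomic position of this CDS index (plus strand: direct mapping)
        off = 0
        for s, e in t.cds_pieces:
            if ci < off + (e - s + 1):
                pos = s + (ci - off)
                break
            off += e - s + 1
        ann = self._annotate_one(genome, t.chrom, pos, alt)
        assert ann.consequence == "stop_gained"
        assert ann.klass == "lof"

    def test_splice_sites_are_lof(self, genome):
        t = genome.transcripts[0]
        donors, acceptors = t.splice_sites()
        seq = genome.sequences[t.chrom]
        for pos in (min(donors), min(acceptors)):
            ref = seq[pos - 1]
            alt = "A" if ref != "A" else "G"
            ann = self._annotate_one(genome, t.chrom, pos, alt)
            assert ann.consequence in ("splice_donor_variant", "splice_acceptor_variant")
            assert ann.klass == "lof"

    def test_reference_mismatch_rejected(self, genome):
        t = genome.transcripts[0]
        pos = t.cds_pieces[0][0]
        ref = genome.sequences[t.chrom][pos - 1]
        wrong = "A" if ref != "A" else "C"
        sites = pd.DataFrame({"chrom": [t.chrom], "pos": [pos], "ref": [wrong], "alt": [ref]})
        with pytest.raises(ValueError, match="mismatch"):
            dl.annotate_consequences(sites, genome.sequences, genome.transcripts)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_translation_oracle(self, seed):
        """Random SNPs across the toy genome agree with re-translation."""
        genome = dl.generate_toy_genome(n_genes=6, cds_len=90, seed=seed, n_exons=2)
        chrom = genome.transcripts[0].chrom
        seq = genome.sequences[chrom]
        rng = np.random.default_rng(seed)
        rows = []
        for pos in rng.choice(len(seq), 150, replace=False) + 1:
            ref = seq[pos - 1]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            rows.append((chrom, int(pos), ref, alt))
        sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"]).sort_values("pos")
        anns = dl.annotate_consequences(sites, genome.sequences, genome.transcripts)
        for row, ann in zip(sites.itertuples(index=False), anns):
            hits = [
                t for t in genome.transcripts
                if t.cds_index(row.pos) is not None
                or row.pos in t.splice_sites()[0] | t.splice_sites()[1]
            ]
            expect = (
                consequence_oracle(hits[0], genome.sequences, row.pos, row.ref, row.alt)
                if hits
                else "non_coding"
            )
            assert ann.consequence == expect, (row, ann)

    def test_gff3_fasta_round_trip(self, genome, tmp_path):
        """Writing and re-reading the toy genome preserves the peptides."""
        fa, gff = tmp_path / "g.fa", tmp_path / "g.gff3"
        genome.write(fa, gff)
        seqs = dl.read_fasta(fa)
        trans = dl.read_gff3(gff)
        assert len(trans) == len(genome.transcripts)
        by_id = {t.gene_id: t for t in genome.transcripts}
        for t in trans:
            assert t.translate(seqs) == by_id[t.gene_id].translate(genome.sequences)

    def test_minus_strand_equals_plus_oracle(self):
        """Peptides on the minus strand match their construction spec."""
        genome = dl.generate_toy_genome(n_genes=2, cds_len=30, seed=1)
        for t in genome.transcripts:
            pep = t.translate(genome.sequences)
            assert pep[0] == "M" and pep.endswith("*")
            assert len(pep) == 30 // 3


class TestPolarize:
    def _gm(self):
        g = np.array([[0, 1], [1, 2], [2, 0]], dtype=np.int8)
        return make_gm(
            g,
            ref=["A", "C", "G"],
            alt=["G", "T", "A"],
            info=[{"AA": "A"}, {"AA": "T"}, {"AA": "C"}],
        )

    def test_aa_tag(self):
        d = dl.polarize(self._gm(), "aa")
        assert list(d) == [1, 0, -1]  # AA=ref; AA=alt; AA matches neither

    def test_reference_policy(self):
        assert list(dl.polarize(self._gm(), "reference")) == [1, 1, 1]

    def test_truth_table_and_mispolarization(self, two_pop_dataset):
        ds = two_pop_dataset
        d_truth = dl.polarize(ds.gm, ds.truth)
        d_ref = dl.polarize(ds.gm, "reference")
        flipped = ds.truth["derived_index"].to_numpy() == 0
        assert (d_truth == ds.truth["derived_index"].to_numpy()).all()
        # the reference policy mispolarizes exactly the ref==derived sites
        assert ((d_ref != d_truth) == flipped).all()


class TestRab:
    def test_duplicated_populations_give_unity(self, two_pop_dataset):
        ds = two_pop_dataset
        gm = ds.gm
        dup = dl.GenotypeMatrix(
            sites=gm.sites,
            genotypes=np.concatenate([gm.genotypes, gm.genotypes], axis=1),
            samples=gm.samples + [s + "_dup" for s in gm.samples],
            populations={**{s: "X" for s in gm.samples},
                         **{s + "_dup": "Y" for s in gm.samples}},
        )
        rep = dl.rab(
            dup, ds.truth["class"].to_numpy(), dl.polarize(dup, ds.truth),
            pops=("X", "Y"),
        )
        r = rep.table["r"].dropna()
        assert np.allclose(r, 1.0)

    def test_point_estimate_invariant_to_site_order(self, two_pop_dataset):
        ds = two_pop_dataset
        gm = ds.gm
        classes = ds.truth["class"].to_numpy()
        derived = dl.polarize(gm, ds.truth)
        rep1 = dl.rab(gm, classes, derived, pops=("A", "B"))
        rng = np.random.default_rng(0)
        perm = rng.permutation(gm.n_sites)
        gm2 = make_gm(
            gm.genotypes[perm],
            positions=np.arange(1, gm.n_sites + 1),
            populations=gm.populations,
        )
        gm2.samples[:] = gm.samples
        rep2 = dl.rab(gm2, classes[perm], derived[perm], pops=("A", "B"))
        t1 = rep1.table.set_index(["class", "zygosity"])["r"]
        t2 = rep2.table.set_index(["class", "zygosity"])["r"]
        pd.testing.assert_series_equal(t1, t2)

    def test_count_partition(self, two_pop_dataset):
        """Het + hom counts equal carrier-site counts, no double counting."""
        ds = two_pop_dataset
        gm = ds.gm
        derived = dl.polarize(gm, ds.truth)
        rep = dl.rab(gm, ds.truth["class"].to_numpy(), derived, pops=("A", "B"))
        per = rep.per_individual
        k = gm.samples[0]
        tot = per[per["sample"] == k]["count"].sum()
        known = derived >= 0
        dc = np.where(derived == 1, gm.genotypes[:, 0], 2 - gm.genotypes[:, 0])
        dc[gm.genotypes[:, 0] == -1] = -1
        classes = ds.truth["class"].to_numpy()
        used = np.isin(classes, ["synonymous", "missense_benign", "missense_deleterious", "lof"])
        expect = int(((dc > 0) & known & used).sum())
        assert tot == expect

    def test_ci_contains_point_estimate(self, two_pop_dataset):
        ds = two_pop_dataset
        rep = dl.rab(
            ds.gm, ds.truth["class"].to_numpy(), dl.polarize(ds.gm, ds.truth),
            pops=("A", "B"),
        )
        ok = rep.table.dropna(subset=["se_log"])
        assert ((ok["ci_low"] <= ok["r"]) & (ok["r"] <= ok["ci_high"])).all()

    def test_mean_b_zero_flagged(self):
        g = np.array([[1, 1, 0, 0]], dtype=np.int8)
        gm = make_gm(g, populations={"s0": "A", "s1": "A", "s2": "B", "s3": "B"})
        rep = dl.rab(gm, np.array(["lof"]), np.array([1]), pops=("A", "B"),
                     classes=("lof",))
        assert any("mean_B = 0" in f for f in rep.flags)
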