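import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from splicescan.dataset import (
    annotated_site_keys,
    boundary_offset,
    downsample_negatives,
    enumerate_negative_sites,
    extract_positive_sites,
    extract_window,
    make_split,
    one_hot,
    split_contigs,
)
from splicescan.formats import GeneRecord, Genome, reverse_complement


def _genome_with_intron(intron_seq: str, flank_len: int = 120):
    """A plus-strand two-exon gene around a given intron sequence."""
    rng = np.random.default_rng(42)
    bases = np.array(list("ACGT"))
    left = "".join(rng.choice(bases, flank_len))
    right = "".join(rng.choice(bases, flank_len))
    seq = left + intron_seq + right
    x, y = flank_len, flank_len + len(intron_seq)
    gene = GeneRecord("c1", 0, len(seq), "+", "g1.t1",
                      blocks=[(0, x), (y, len(seq))])
    return Genome({"c1": seq}), gene, x, y


class TestPositiveSites:
    def test_plus_strand_offsets(self):
        genome, gene, x, y = _genome_with_intron("GT" + "A" * 96 + "AG")
        sites = extract_positive_sites(genome, [gene])
        assert {(s.site_type, s.offset, s.strand) for s in sites} == {
            ("donor", x, "+"),
            ("acceptor", y, "+"),
        }
        donor = next(s for s in sites if s.site_type == "donor")
        assert donor.window[100:102] == "GT"
        acceptor = next(s for s in sites if s.site_type == "acceptor")
        assert acceptor.window[100:102] == "AG"

    def test_minus_strand_windows_match_reverse_complement_oracle(self):
        """Mirroring the genome and flipping the strand must give windows
        identical to the plus-strand case."""
        genome, gene, x, y = _genome_with_intron("GT" + "A" * 96 + "AG")
        plus_sites = extract_positive_sites(genome, [gene])

        seq = genome["c1"]
        L = len(seq)
        mirrored = Genome({"c1": reverse_complement(seq)})
        # the intron [x, y) maps to [L-y, L-x) on the mirrored contig
        mgene = GeneRecord("c1", 0, L, "-", "g1.t1",
                           blocks=[(0, L - y), (L - x, L)])
        assert mirrored["c1"][L - y : L - y + 2] == "CT"  # rc of AG
        minus_sites = extract_positive_sites(mirrored, [mgene])
        assert {s.site_type: s.window for s in minus_sites} == {
            s.site_type: s.window for s in plus_sites
        }
        assert {s.site_type: s.offset for s in minus_sites} == {
            "donor": L - x, "acceptor": L - y
        }

    def test_non_gt_donor_skipped_but_ag_acceptor_kept(self):
        genome, gene, x, y = _genome_with_intron("GC" + "A" * 96 + "AG")
        sites = extract_positive_sites(genome, [gene])
        assert [s.site_type for s in sites] == ["acceptor"]

    def test_shared_junction_collapsed_across_isoforms(self):
        genome, gene, x, y = _genome_with_intron("GT" + "A" * 96 + "AG")
        iso2 = GeneRecord(gene.contig, gene.start, gene.end, gene.strand,
                          "g1.t2", gene_id="g1", blocks=gene.blocks)
        assert len(extract_positive_sites(genome, [gene, iso2])) == 2


class TestNegativeSites:
    def test_opposite_strand_rule(self):
        # GT at forward position 150 inside a plus-strand gene body is a
        # candidate negative donor on the minus strand only if its minus
        # reading is GT, i.e. forward "AC"
        genome, gene, x, y = _genome_with_intron("GT" + "A" * 96 + "AG")
        negs = enumerate_negative_sites(genome, [gene])
        assert negs, "gene body should contain opposite-strand candidates"
        assert all(n.strand == "-" for n in negs)  # gene is on +
        assert all(gene.start <= n.pos < gene.end for n in negs)
        ann = annotated_site_keys(genome, [gene])
        assert all(
            (n.contig, n.offset, n.strand, n.site_type) not in ann for n in negs
        )

    def test_intergenic_candidates_not_emitted(self):
        genome, gene, x, y = _genome_with_intron("GT" + "A" * 96 + "AG")
        short_gene = GeneRecord("c1", x - 10, y + 10, "+", "g1.t1",
                                blocks=[(x - 10, x), (y, y + 10)])
        negs = enumerate_negative_sites(genome, [short_gene])
        assert all(short_gene.start <= n.pos < short_gene.end for n in negs)

    def test_both_strand_overlap_excluded(self):
        genome, gene, x, y = _genome_with_intron("GT" + "A" * 96 + "AG")
        L = len(genome["c1"])
        antisense = GeneRecord("c1", 0, L, "-", "g2.t1", blocks=[(0, L)])
        negs = enumerate_negative_sites(genome, [gene, antisense])
        assert negs == []  # everything is covered on both strands


class TestDownsampling:
    def _examples(self, n, site_type, label):
        return [
            type("E", (), {"site_type": site_type, "label": label})()
            for _ in range(n)
        ]

    def test_exact_ratio_with_ample_supply(self):
        pos = self._examples(10, "donor", 1)
        neg = self._examples(100, "donor", 0)
        assert len(downsample_negatives(pos, neg, ratio=3, seed=0)) == 30

    def test_short_supply_keeps_all(self):
        pos = self._examples(10, "donor", 1)
        neg = self._examples(20, "donor", 0)
        assert len(downsample_negatives(pos, neg, ratio=3, seed=0)) == 20

    def test_per_site_type_and_determinism(self):
        pos = self._examples(4, "donor", 1) + self._examples(2, "acceptor", 1)
        neg = self._examples(50, "donor", 0) + self._examples(50, "acceptor", 0)
        picked = downsample_negatives(pos, neg, ratio=3, seed=1)
        assert sum(1 for e in picked if e.site_type == "donor") == 12
        assert sum(1 for e in picked if e.site_type == "acceptor") == 6
        again = downsample_negatives(pos, neg, ratio=3, seed=1)
        assert [id(e) for e in picked] == [id(e) for e in again]


class TestWindows:
    def test_window_lengths(self):
        genome = Genome({"c1": "A" * 500})
        for flank in (50, 100, 150):
            w = extract_window(genome, "c1", 250, "+", flank)
            assert len(w) == 2 * flank + 2

    def test_boundary_window_starts_at_zero(self):
        genome = Genome({"c1": "ACGT" * 100})
        assert extract_window(genome, "c1", 100, "+", 100) == genome["c1"][0:202]
        assert extract_window(genome, "c1", 99, "+", 100) is None
        assert extract_window(genome, "c1", 299, "+", 100) is None

    def test_minus_strand_is_reverse_complemented(self):
        genome = Genome({"c1": "ACGTACGTACGT"})
        w = extract_window(genome, "c1", 5, "-", 2)
        assert w == reverse_complement(genome["c1"][3:9])


class TestOneHot:
    def test_acgt_is_identity_permutation(self):
        m = one_hot("ACGT")
        assert np.array_equal(m, np.eye(4, dtype=np.float32))

    def test_n_gives_zero_column(self):
        m = one_hot("ANT")
        assert m[:, 1].sum() == 0
        assert np.array_equal(m.sum(axis=0), [1, 0, 1])

    def test_rejects_other_characters(self):
        with pytest.raises(ValueError):
            one_hot("ACGU")

    @given(st.text(alphabet="ACGTN", min_size=1, max_size=60))
    def test_reverse_complement_identity(self, w):
        lhs = one_hot(reverse_complement(w))
        rhs = one_hot(w)[::-1, ::-1]  # A<->T, C<->G row swap + position flip
        assert np.array_equal(lhs, rhs)


class TestMakeSplit:
    def test_contig_parity(self, small_sim):
        _, genome, _ = small_sim
        odd, even = split_contigs(genome)
        names = genome.names()
        assert odd == names[0::2] and even == names[1::2]

    def test_gene_level_80_20(self, small_sim):
        _, genome, genes = small_sim
        split = make_split(genome, genes, seed=0, with_test=False)
        odd = set(split_contigs(genome)[0])
        odd_gene_ids = {g.gene_id for g in genes if g.contig in odd}
        n = len(odd_gene_ids)
        train_pos = sum(1 for e in split.train if e.label == 1)
        val_pos = sum(1 for e in split.validation if e.label == 1)
        # 8 positive sites per 5-exon gene; counts follow the 80/20 split
        assert train_pos == 8 * int(n * 0.8 + 0.5)
        assert train_pos + val_pos == 8 * n

    def test_no_junction_leaks_between_partitions(self, small_split):
        train_keys = {
            (e.contig, e.offset, e.strand, e.site_type)
            for e in small_split.train if e.label == 1
        }
        val_keys = {
            (e.contig, e.offset, e.strand, e.site_type)
            for e in small_split.validation if e.label == 1
        }
        assert train_keys.isdisjoint(val_keys)

    def test_exact_1_to_3_ratio(self, small_split):
        for part in (small_split.train, small_split.validation):
            pos = sum(1 for e in part if e.label == 1)
            neg = sum(1 for e in part if e.label == 0)
            assert neg == 3 * pos

    def test_every_center_is_gt_or_ag(self, small_split):
        for part in (small_split.train, small_split.validation, small_split.test):
            for e in part:
                want = "GT" if e.site_type == "donor" else "AG"
                assert e.window[100:102] == want

    def test_test_set_positives_equal_even_contig_annotation(self, small_sim, small_split):
        _, genome, genes = small_sim
        even = set(split_contigs(genome)[1])
        even_keys = {
            k for k in annotated_site_keys(genome, genes) if k[0] in even
        }
        test_pos = {
            (e.contig, e.offset, e.strand, e.site_type)
            for e in small_split.test if e.label == 1
        }
        assert test_pos == even_keys

    def test_requires_genes_on_odd_contigs(self, small_sim):
        _, genome, genes = small_sim
        odd = set(split_contigs(genome)[0])
        even_only = [g for g in genes if g.contig not in odd]
        with pytest.raises(ValueError, match="odd contigs"):
            make_split(genome, even_only, seed=0, with_test=False)


def test_boundary_offset_round_trip():
    from splicescan.dataset import pos_from_boundary

    for strand in "+-":
        for site_type in ("donor", "acceptor"):
            off = boundary_offset(500, strand, site_type)
            assert pos_from_boundary(off, strand, site_type) == 500
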