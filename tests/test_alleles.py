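"""Dereplication, allele matrix and resolvability statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster import hierarchy

from ribresolve.alleles import (
    AlleleMatrix,
    allele_multiplicity,
    build_allele_matrix,
    dereplicate,
    fmt_pct,
    normalize_orientation,
    species_overlap,
    ward_order,
    write_reports,
)
from ribresolve.genes import UNSPECIFIED, GenomeRecord
from ribresolve.ispcr import Amplicon, PrimerSite


def _amp(seq: str, genome="G1", contig="c1", start=0) -> Amplicon:
    site = PrimerSite(contig, start, start + 1, "+", 0, 0, 0)
    return Amplicon(genome, contig, start, start + len(seq), "+", seq, site, site)


def _matrix(rows, genome_ids=None, species=None) -> AlleleMatrix:
    rows = np.asarray(rows)
    genome_ids = genome_ids or [f"G{i+1}" for i in range(rows.shape[0])]
    species = species or {g: f"sp{i+1}" for i, g in enumerate(genome_ids)}
    counts = pd.DataFrame(rows, index=pd.Index(genome_ids, name="genome_id"),
                          columns=list(range(1, rows.shape[1] + 1)))
    return AlleleMatrix(counts=counts, species_of=species)


class TestNormalizeOrientation:
    @pytest.mark.parametrize(
        "seq,mode,expected",
        [
            ("AACG", "lexicographic", "AACG"),
            ("CGTT", "lexicographic", "AACG"),
            ("ACGT", "lexicographic", "ACGT"),
            ("CGTT", "as_is", "CGTT"),
            ("cgtu", "as_is", "CGTT"),
        ],
    )
    def test_modes(self, seq, mode, expected):
        assert normalize_orientation(seq, mode) == expected

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            normalize_orientation("ACGT", "upside_down")


class TestDereplicate:
    def test_size_major_numbering(self):
        clusters = dereplicate([_amp("ACGA"), _amp("ACGT"), _amp("ACGT")])
        assert [(c.allele_id, c.sequence, c.size) for c in clusters] == [
            (1, "ACGT", 2), (2, "ACGA", 1)]

    def test_all_distinct_all_singletons(self, rng):
        seqs = {"".join("ACGT"[i] for i in rng.integers(0, 4, 30))
                for _ in range(80)}
        clusters = dereplicate([_amp(s) for s in seqs])
        assert len(clusters) == len(seqs)
        assert all(c.size == 1 for c in clusters)

    def test_lexicographic_merges_rc_duplicates(self):
        clusters = dereplicate([_amp("AACG"), _amp("CGTT")],
                               orientation="lexicographic")
        assert len(clusters) == 1 and clusters[0].size == 2

    def test_empty_input(self):
        assert dereplicate([]) == []

    @settings(max_examples=30, derandomize=True)
    @given(st.permutations(list(range(7))))
    def test_permutation_invariant_composition(self, order):
        amps = [_amp(s) for s in ("AAAA", "AAAA", "CCCC", "GGGG", "GGGG",
                                  "GGGG", "TTTT")]
        shuffled = [amps[i] for i in order]
        base = {(c.sequence, c.size) for c in dereplicate(amps)}
        assert {(c.sequence, c.size) for c in dereplicate(shuffled)} == base

    def test_cluster_count_matches_set_oracle(self, rng):
        seqs = ["".join("ACGT"[i] for i in rng.integers(0, 4, 5))
                for _ in range(200)]
        clusters = dereplicate([_amp(s) for s in seqs])
        assert len(clusters) == len(set(seqs))
        assert sum(c.size for c in clusters) == len(seqs)


class TestBuildMatrix:
    def _genomes(self, *ids):
        return [GenomeRecord(g, "Genus", f"sp{i}", {"c": "ACGT"})
                for i, g in enumerate(ids, start=1)]

    def test_single_genome_single_allele(self):
        clusters = dereplicate([_amp("ACGT", "GA") for _ in range(7)])
        m = build_allele_matrix(clusters, self._genomes("GA"))
        assert m.counts.to_numpy().tolist() == [[7]]
        assert m.total == 7

    def test_two_genomes_shared_allele(self):
        amps = ([_amp("AAAA", "GA")] * 3 + [_amp("AAAA", "GB")] * 2
                + [_amp("CCCC", "GB")])
        m = build_allele_matrix(dereplicate(amps), self._genomes("GA", "GB"))
        assert m.counts.to_numpy().tolist() == [[3, 0], [2, 1]]

    def test_shared_allele_column_two_nonzero_rows(self):
        amps = [_amp(s, "GA") for s in ("AAAA", "CCCC", "GGGG")] + [
            _amp("AAAA", "GB")]
        m = build_allele_matrix(dereplicate(amps), self._genomes("GA", "GB"))
        assert int((m.counts > 0).loc["GA"].sum()) == 3
        # exactly one allele column is populated by both genomes
        assert int(((m.counts > 0).sum() == 2).sum()) == 1

    def test_unknown_genome_rejected(self):
        clusters = dereplicate([_amp("ACGT", "GZ")])
        with pytest.raises(ValueError, match="GZ"):
            build_allele_matrix(clusters, self._genomes("GA"))

    def test_zero_amplicon_genome_keeps_row(self):
        clusters = dereplicate([_amp("ACGT", "GA")])
        m = build_allele_matrix(clusters, self._genomes("GA", "GB"))
        assert m.counts.loc["GB"].sum() == 0


class TestStatistics:
    def test_multiplicity_basic(self):
        flags, pct = allele_multiplicity(_matrix([[7, 0], [3, 2]]))
        assert flags.tolist() == [False, True]
        assert pct == 50.0
        assert fmt_pct(pct) == "50.00"

    def test_multiplicity_none_flagged(self):
        _, pct = allele_multiplicity(_matrix([[4, 0], [0, 2]]))
        assert pct == 0.0

    def test_multiplicity_rounding_format(self):
        m = _matrix([[1, 1]] * 3 + [[1, 0]] * 7)
        _, pct = allele_multiplicity(m)
        assert fmt_pct(pct) == "30.00"

    def test_multiplicity_rejects_empty(self):
        with pytest.raises(ValueError):
            allele_multiplicity(_matrix(np.zeros((0, 1), dtype=int), [], {}))

    def test_overlap_two_of_three_species(self):
        # sp1 and sp2 share allele 1; sp3 only carries allele 2
        m = _matrix([[2, 0], [1, 0], [0, 3]])
        rep = species_overlap(m)
        assert rep.flagged_species == {"sp1", "sp2"}
        assert fmt_pct(rep.overlap_pct) == "66.67"
        assert rep.indistinguishable_groups == [frozenset({"sp1", "sp2"})]

    def test_overlap_all_share_one_allele(self):
        rep = species_overlap(_matrix([[1], [1], [1]]))
        assert rep.overlap_pct == 100.0
        assert rep.indistinguishable_groups == [frozenset({"sp1", "sp2", "sp3"})]

    def test_genome_sharing_three_species_separately(self):
        # G1 has three alleles, each shared with a different species
        m = _matrix([[1, 1, 1, 0], [1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 1, 1]])
        rep = species_overlap(m)
        conf = rep.genome_confusion
        assert conf.loc["G1", ["G2", "G3", "G4"]].all()
        assert rep.flagged_species == {"sp1", "sp2", "sp3", "sp4"}
        assert rep.indistinguishable_groups == [
            frozenset({"sp1", "sp2", "sp3", "sp4"})]

    def test_confusion_symmetric_true_diagonal(self):
        rep = species_overlap(_matrix([[1, 0], [0, 1], [1, 1]]))
        conf = rep.genome_confusion.to_numpy()
        assert (conf == conf.T).all() and conf.diagonal().all()

    def test_unspecified_excluded_from_percentage(self):
        # the unclassified genome shares allele 1 with sp1 but neither
        # flags sp1 nor enters the denominator
        m = _matrix([[1, 0], [0, 1], [1, 0]],
                    species={"G1": "sp1", "G2": "sp2", "G3": UNSPECIFIED})
        rep = species_overlap(m)
        assert rep.overlap_pct == 0.0
        assert rep.n_named_species == 2
        assert rep.genome_confusion.loc["G1", "G3"]
        assert any(UNSPECIFIED in (a, b) for a, b, _ in rep.species_pairs)

    def test_no_named_species_undefined(self):
        m = _matrix([[1], [1]], species={"G1": UNSPECIFIED, "G2": UNSPECIFIED})
        rep = species_overlap(m)
        assert rep.overlap_pct is None
        assert fmt_pct(rep.overlap_pct) == "NA"

    def test_overlap_monotone_under_added_amplicon(self):
        base = _matrix([[1, 0, 0], [0, 1, 0], [0, 0, 1]])
        before = species_overlap(base)
        grown = base.counts.copy()
        grown.loc["G2", 1] = 1  # G2 now also carries allele 1
        after = species_overlap(AlleleMatrix(grown, base.species_of))
        assert before.flagged_species <= after.flagged_species
        assert (before.genome_confusion.to_numpy()
                <= after.genome_confusion.to_numpy()).all()


class TestWardOrder:
    def test_identical_rows_adjacent(self):
        m = _matrix([[5, 0, 0], [0, 0, 9], [5, 0, 0]])
        order = ward_order(m, "rows")
        pos = {i: order.index(i) for i in range(3)}
        assert abs(pos[0] - pos[2]) == 1

    def test_deterministic(self):
        m = _matrix([[1, 0], [0, 1]])
        assert ward_order(m, "rows") == ward_order(m, "rows")
        assert ward_order(m, "cols") == ward_order(m, "cols")

    def test_single_item_identity(self):
        m = _matrix([[1, 2]])
        assert ward_order(m, "rows") == [0]

    def test_block_structure_consistent_with_linkage(self):
        """On a 5x3 matrix with two blocks the leaf order keeps blocks
        contiguous and is one of the orders realizable from the linkage."""
        rows = [[9, 8, 0], [8, 9, 0], [9, 9, 1], [0, 1, 9], [1, 0, 8]]
        m = _matrix(rows)
        order = ward_order(m, "rows")
        blocks = [{0, 1, 2}, {3, 4}]
        labels = ["A" if i in blocks[0] else "B" for i in order]
        assert labels in (["A"] * 3 + ["B"] * 2, ["B"] * 2 + ["A"] * 3)

        linkage = hierarchy.linkage(np.asarray(rows, dtype=float), "ward")

        def leaf_orders(node):
            if node < 5:
                return [[node]]
            left, right = int(linkage[node - 5][0]), int(linkage[node - 5][1])
            out = []
            for a in leaf_orders(left):
                for b in leaf_orders(right):
                    out.append(a + b)
                    out.append(b + a)
            return out

        assert order in leaf_orders(2 * 5 - 2)


class TestWriteReports:
    def test_single_allele_outputs(self, tmp_path):
        clusters = dereplicate([_amp("ACGTACGT", "GA") for _ in range(7)])
        genomes = [GenomeRecord("GA", "Genus", "sp1", {"c": "ACGT"})]
        m = build_allele_matrix(clusters, genomes)
        rep = species_overlap(m)
        files = write_reports(m, rep, tmp_path, clusters=clusters)
        matrix_lines = (tmp_path / "allele_matrix.tsv").read_text().splitlines()
        assert len(matrix_lines) == 2  # header + one genome row
        fasta = (tmp_path / "alleles.fasta").read_text()
        assert fasta.startswith(">allele_1;size=7\n")
        summary = (tmp_path / "summary.tsv").read_text().splitlines()[1].split("\t")
        assert summary == ["1", "1", "1", "0.00", "0.00"]

    def test_empty_input_still_writes(self, tmp_path, caplog):
        genomes = [GenomeRecord("GA", "Genus", "sp1", {"c": "ACGT"})]
        m = build_allele_matrix([], genomes)
        rep = species_overlap(m)
        import logging

        with caplog.at_level(logging.WARNING, logger="ribresolve.alleles"):
            write_reports(m, rep, tmp_path, clusters=[])
        assert "no amplicons" in caplog.text
        assert (tmp_path / "allele_matrix.tsv").exists()
        assert (tmp_path / "summary.tsv").exists()

    def test_shared_allele_fixture_report_text(self, tmp_path):
        m = _matrix([[1], [1], [1]])
        rep = species_overlap(m)
        write_reports(m, rep, tmp_path)
        text = (tmp_path / "overlap_report.txt").read_text()
        assert "group_1\tsp1, sp2, sp3" in text
        assert "species_overlap_pct\t100.00" in text

    def test_plots_written(self, tmp_path):
        m = _matrix([[5, 0], [0, 3], [5, 1]])
        rep = species_overlap(m)
        write_reports(m, rep, tmp_path, make_plots=True)
        assert (tmp_path / "heatmap_alleles.png").exists()
        assert (tmp_path / "heatmap_confusion.png").exists()
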