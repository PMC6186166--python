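"""Readers/writers round-trip exactly and malformed inputs raise located
errors instead of being coerced."""

import numpy as np
import pytest

import sigdepth as sd


def _write_counts_files(tmp_path, rows, groups_lines):
    counts = tmp_path / "counts.tsv"
    counts.write_text("\n".join(rows) + "\n")
    groups = tmp_path / "groups.tsv"
    groups.write_text("\n".join(groups_lines) + "\n")
    return counts, groups


class TestReadCounts:
    HEADER = "gene\ts1\ts2\ts3\ts4"
    GROUPS = ["s1\tA", "s2\tA", "s3\tB", "s4\tB"]

    def test_well_formed(self, tmp_path):
        counts, groups = _write_counts_files(
            tmp_path,
            [self.HEADER, "g1\t1\t2\t3\t4", "g2\t0\t0\t0\t0", "g3\t9\t8\t7\t6"],
            self.GROUPS,
        )
        cm = sd.read_counts(counts, groups)
        assert cm.n_genes == 3 and cm.n_samples == 4
        assert cm.sample_ids == ["s1", "s2", "s3", "s4"]  # header order
        assert cm.groups == ["A", "A", "B", "B"]

    def test_non_integer_entry_names_gene_and_sample(self, tmp_path):
        counts, groups = _write_counts_files(
            tmp_path, [self.HEADER, "g1\t1\t2.5\t3\t4", "g2\t1\t1\t1\t1"], self.GROUPS
        )
        with pytest.raises(sd.FormatError, match=r"g1.*s2"):
            sd.read_counts(counts, groups)

    def test_non_numeric_entry(self, tmp_path):
        counts, groups = _write_counts_files(
            tmp_path, [self.HEADER, "g1\t1\tNA\t3\t4"], self.GROUPS
        )
        with pytest.raises(sd.FormatError, match="non-numeric"):
            sd.read_counts(counts, groups)

    def test_negative_entry(self, tmp_path):
        counts, groups = _write_counts_files(
            tmp_path, [self.HEADER, "g1\t1\t-2\t3\t4"], self.GROUPS
        )
        with pytest.raises(sd.FormatError, match="negative"):
            sd.read_counts(counts, groups)

    def test_duplicate_gene(self, tmp_path):
        counts, groups = _write_counts_files(
            tmp_path, [self.HEADER, "g1\t1\t2\t3\t4", "g1\t1\t2\t3\t4"], self.GROUPS
        )
        with pytest.raises(sd.FormatError, match="duplicate gene"):
            sd.read_counts(counts, groups)

    def test_third_group_level(self, tmp_path):
        counts, groups = _write_counts_files(
            tmp_path,
            [self.HEADER, "g1\t1\t2\t3\t4"],
            ["s1\tA", "s2\tA", "s3\tB", "s4\tC"],
        )
        with pytest.raises(sd.ContrastError):
            sd.read_counts(counts, groups)

    def test_sample_missing_from_groups(self, tmp_path):
        counts, groups = _write_counts_files(
            tmp_path, [self.HEADER, "g1\t1\t2\t3\t4"], ["s1\tA", "s2\tA", "s3\tB"]
        )
        with pytest.raises(sd.ConsistencyError, match="s4"):
            sd.read_counts(counts, groups)

    def test_write_read_fixed_point(self, tmp_path, tiny_counts):
        c1, g1 = tmp_path / "c.tsv", tmp_path / "g.tsv"
        sd.write_counts(tiny_counts, c1, g1)
        cm = sd.read_counts(c1, g1)
        assert cm.gene_ids == tiny_counts.gene_ids
        assert np.array_equal(cm.counts, tiny_counts.counts)
        assert cm.groups == tiny_counts.groups


class TestSignatureIO:
    def test_gmt_round_trip(self, tmp_path):
        sig = sd.GeneSignature(
            name="S", up=frozenset({"g1", "g2"}), down=frozenset({"g3"}),
            provenance={"f": 0.5, "iteration": 3},
        )
        path = tmp_path / "s.gmt"
        sd.write_signature_gmt(sig, path)
        back = sd.read_signature_gmt(path)
        assert back.up == sig.up and back.down == sig.down
        assert back.provenance["f"] == 0.5 and back.provenance["iteration"] == 3

    def test_gmt_overlap_is_integrity_error(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("S_UP\tna\tg1\tg5\nS_DN\tna\tg5\n")
        with pytest.raises(sd.IntegrityError):
            sd.read_signature_gmt(path)

    def test_gmt_missing_pair(self, tmp_path):
        path = tmp_path / "half.gmt"
        path.write_text("S_UP\tna\tg1\n")
        with pytest.raises(sd.FormatError, match="paired"):
            sd.read_signature_gmt(path)

    def test_empty_down_round_trips(self, tmp_path):
        sig = sd.GeneSignature(name="S", up=frozenset({"g1"}), down=frozenset())
        path = tmp_path / "s.gmt"
        sd.write_signature_gmt(sig, path)
        back = sd.read_signature_gmt(path)
        assert back.down == frozenset() and back.up == {"g1"}

    def test_grp_round_trip(self, tmp_path):
        sig = sd.GeneSignature(name="S", up=frozenset({"g1", "g2"}), down=frozenset({"g4"}))
        sd.write_signature_grp(sig, tmp_path / "S")
        back = sd.read_signature_grp(tmp_path / "S")
        assert back.up == sig.up and back.down == sig.down

    def test_overlapping_sets_rejected_at_construction(self):
        with pytest.raises(sd.IntegrityError):
            sd.GeneSignature(name="S", up=frozenset({"g1"}), down=frozenset({"g1"}))


class TestReferenceLibraryIO:
    def _long_tsv(self, tmp_path, drop_last=False):
        lines = ["perturbagen\tcell_line\tgene\tscore"]
        for p in ("p1", "p2"):
            for c in ("CL1", "CL2"):
                for i, g in enumerate(["g1", "g2", "g3", "g4", "g5"]):
                    if drop_last and (p, c, g) == ("p1", "CL1", "g5"):
                        continue
                    lines.append(f"{p}\t{c}\t{g}\t{0.1 * i}")
        path = tmp_path / "lib.tsv"
        path.write_text("\n".join(lines) + "\n")
        return path

    def test_long_tsv(self, tmp_path):
        lib = sd.read_reference_library(self._long_tsv(tmp_path))
        assert lib.n_profiles == 4
        assert lib.gene_universe == ["g1", "g2", "g3", "g4", "g5"]
        assert lib.n_imputed == 0

    def test_missing_gene_imputed_zero(self, tmp_path):
        lib = sd.read_reference_library(self._long_tsv(tmp_path, drop_last=True))
        assert lib.n_imputed == 1
        col = [
            j for j in range(lib.n_profiles)
            if (lib.perturbagens[j], lib.cell_lines[j]) == ("p1", "CL1")
        ][0]
        assert lib.scores[lib.gene_universe.index("g5"), col] == 0.0

    def test_tags_file(self, tmp_path):
        tags = tmp_path / "tags.tsv"
        tags.write_text("CL2\tneuronal\n")
        lib = sd.read_reference_library(self._long_tsv(tmp_path), tags)
        assert "neuronal" in lib.cell_line_tags["CL2"]

    def test_duplicate_triple_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text(
            "perturbagen\tcell_line\tgene\tscore\n"
            "p1\tCL1\tg1\t0.5\np1\tCL1\tg1\t0.7\n"
        )
        with pytest.raises(sd.FormatError, match="duplicated"):
            sd.read_reference_library(path)

    def test_non_numeric_score_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "perturbagen\tcell_line\tgene\tscore\np1\tCL1\tg1\thigh\n"
        )
        with pytest.raises(sd.FormatError, match="non-numeric"):
            sd.read_reference_library(path)

    def test_long_round_trip(self, tmp_path, default_study):
        _, _, library, _ = default_study
        path, tags = tmp_path / "lib.tsv", tmp_path / "tags.tsv"
        sd.write_library_long(library, path, tags)
        back = sd.read_reference_library(path, tags)
        assert back.gene_universe == library.gene_universe
        # writer emits profiles in column order; reader preserves it
        assert back.perturbagens == library.perturbagens
        np.testing.assert_allclose(back.scores, library.scores)
        assert back.cell_line_tags["CL1"] == {"neuronal"}

    def test_gct_round_trip(self, tmp_path, default_study):
        _, _, library, _ = default_study
        path = tmp_path / "lib.gct"
        sd.write_library_gct(library, path)
        back = sd.read_reference_library(path)
        assert back.gene_universe == library.gene_universe
        np.testing.assert_allclose(back.scores, library.scores)


class TestConnectionResult:
    def test_direction_from_score_sign(self):
        rev = sd.ConnectionResult("p", -0.4, 0.01, 0.02, True)
        prog = sd.ConnectionResult("p", 0.4, 0.01, 0.02, True)
        zero = sd.ConnectionResult("p", 0.0, 1.0, 1.0, False)
        assert (rev.direction, prog.direction, zero.direction) == ("rev", "prog", None)

    def test_zero_score_cannot_be_significant(self):
        with pytest.raises(sd.IntegrityError):
            sd.ConnectionResult("p", 0.0, 0.01, 0.02, True)

    def test_q_below_p_rejected(self):
        with pytest.raises(sd.IntegrityError):
            sd.ConnectionResult("p", 0.5, 0.05, 0.01, False)
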