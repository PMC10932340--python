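"""Variant parsing, coding-sequence enumeration and input readers."""

import json

import numpy as np
import pytest
from Bio.Seq import Seq

from vfipred.variants import (
    CodingSequence,
    DataValidationError,
    ProteinVariant,
    VariantParseError,
    enumerate_missense,
    missense_possible_per_position,
    parse_variant,
    read_allele_table,
    read_domain_map,
    read_labeled_dataset,
    read_plddt,
)


class TestParseVariant:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("G256E", ("G", 256, "E")),
            ("p.Asp488Glu", ("D", 488, "E")),
            ("p.Gly256Glu", ("G", 256, "E")),
            ("M1V", ("M", 1, "V")),
            ("a501p", ("A", 501, "P")),
        ],
    )
    def test_accepted_forms(self, text, expected):
        v = parse_variant(text)
        assert (v.ref_aa, v.position, v.alt_aa) == expected

    @pytest.mark.parametrize(
        "text",
        ["G256G", "X256E", "G0E", "", "p.Gly256Ter", "G256*", "frameshift", "G-5E"],
    )
    def test_rejected_forms(self, text):
        with pytest.raises(VariantParseError):
            parse_variant(text)

    def test_round_trip_identity_sampled(self, rng):
        """String form round-trips over sampled ref/alt pairs and positions."""
        aas = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(300):
            ref, alt = rng.choice(list(aas), size=2, replace=False)
            pos = int(rng.integers(1, 1000))
            v = ProteinVariant(ref, pos, alt)
            assert parse_variant(str(v)) == v
            assert parse_variant(v.long_form) == v


def _oracle_counts(cds: CodingSequence):
    """Independent brute-force oracle: mutate, translate with biopython, compare."""
    seq = cds.nucleotides
    nonsyn = stops = syn = 0
    distinct = set()
    for i in range(len(seq)):
        for base in "ACGT":
            if base == seq[i]:
                continue
            mutated = seq[:i] + base + seq[i + 1 :]
            codon_idx = i // 3
            ref_aa = str(Seq(seq[codon_idx * 3 : codon_idx * 3 + 3]).translate())
            alt_aa = str(Seq(mutated[codon_idx * 3 : codon_idx * 3 + 3]).translate())
            if alt_aa == ref_aa:
                syn += 1
            else:
                nonsyn += 1
                if alt_aa == "*":
                    stops += 1
                elif ref_aa != "*":
                    distinct.add((codon_idx + 1, alt_aa))
    return nonsyn, stops, len(distinct), syn


class TestEnumerateMissense:
    def test_met_trp_dicodon(self):
        """Met and Trp have no synonymous changes; all 18 substitutions are
        non-synonymous, two of them stop-introducing."""
        s = enumerate_missense(CodingSequence("ATGTGG"))
        assert s.nonsyn_substitutions == 18
        assert s.stop_introducing == 2
        assert s.distinct_missense_variants == 11
        assert s.synonymous == 0

    def test_glycine_codon(self):
        s = enumerate_missense(CodingSequence("GGG"))
        oracle = _oracle_counts(CodingSequence("GGG"))
        assert s.synonymous == 3  # third-position wobble
        assert (s.nonsyn_substitutions, s.stop_introducing, s.distinct_missense_variants, s.synonymous) == oracle

    def test_empty_sequence(self):
        s = enumerate_missense(CodingSequence(""))
        assert (s.nonsyn_substitutions, s.stop_introducing, s.distinct_missense_variants, s.synonymous) == (0, 0, 0, 0)

    def test_not_multiple_of_three(self):
        with pytest.raises(DataValidationError):
            CodingSequence("ATGT")

    def test_oracle_equivalence_random_cds(self, rng):
        """Agreement with the brute-force translate-and-compare oracle on
        100 random coding sequences, plus the partition identity."""
        bases = np.array(list("ACGT"))
        for _ in range(100):
            n_codons = int(rng.integers(1, 61))
            seq = "".join(bases[rng.integers(4, size=3 * n_codons)])
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cds = CodingSequence(seq)
            s = enumerate_missense(cds)
            assert (
                s.nonsyn_substitutions,
                s.stop_introducing,
                s.distinct_missense_variants,
                s.synonymous,
            ) == _oracle_counts(cds)
            assert s.nonsyn_substitutions + s.synonymous == 9 * cds.codon_count

    def test_internal_stop_warns(self):
        with pytest.warns(UserWarning, match="internal stop"):
            CodingSequence("TAAATG")

    def test_missense_possible_consistent_with_enumeration(self):
        cds = CodingSequence("ATGTGGGGG")
        per_pos = missense_possible_per_position(cds)
        assert sum(per_pos) == enumerate_missense(cds).distinct_missense_variants


class TestAlleleTable:
    def _write(self, tmp_path, rows):
        path = tmp_path / "alleles.tsv"
        lines = ["variant\tallele_count\ttotal_alleles\tsource"] + rows
        path.write_text("\n".join(lines) + "\n")
        return path

    def test_two_sources_union(self, tmp_path):
        path = self._write(
            tmp_path, ["G2E\t3\t150000\tv2", "A3T\t5\t280000\tv3"]
        )
        table = read_allele_table(path)
        assert len(table) == 2

    def test_same_variant_in_both_sources_retained(self, tmp_path):
        path = self._write(
            tmp_path, ["G2E\t3\t150000\tv2", "G2E\t5\t280000\tv3"]
        )
        assert len(read_allele_table(path)) == 2  # dedup deferred to merge

    def test_negative_count_rejected(self, tmp_path):
        path = self._write(tmp_path, ["G2E\t-1\t150000\tv2"])
        with pytest.raises(DataValidationError):
            read_allele_table(path)

    def test_count_exceeding_total_rejected(self, tmp_path):
        path = self._write(tmp_path, ["G2E\t9\t5\tv2"])
        with pytest.raises(DataValidationError):
            read_allele_table(path)

    def test_duplicate_variant_source_rejected(self, tmp_path):
        path = self._write(tmp_path, ["G2E\t1\t10\tv2", "G2E\t2\t10\tv2"])
        with pytest.raises(DataValidationError):
            read_allele_table(path)

    def test_malformed_variant_names_row(self, tmp_path):
        path = self._write(tmp_path, ["G2G\t1\t10\tv2"])
        with pytest.raises(DataValidationError, match="row 1"):
            read_allele_table(path)


def _write_ca_pdb(path, values):
    lines = []
    for i, v in enumerate(values, start=1):
        lines.append(
            f"ATOM  {i:>5}  CA  ALA A{i:>4}    {0.0:8.3f}{0.0:8.3f}{float(i):8.3f}"
            f"{1.00:6.2f}{v:6.2f}           C"
        )
    path.write_text("\n".join(lines) + "\nEND\n")


class TestPlddt:
    def test_constant_profile(self, tmp_path):
        path = tmp_path / "m.pdb"
        _write_ca_pdb(path, [90.0] * 10)
        profile = read_plddt(path)
        assert len(profile) == 10
        assert all(v == 90.0 for v in profile.values)

    def test_json_matches_pdb(self, tmp_path):
        values = [50.0, 61.25, 72.5, 88.0]
        pdb = tmp_path / "m.pdb"
        _write_ca_pdb(pdb, values)
        (tmp_path / "m.json").write_text(json.dumps({"plddt": values}))
        from_pdb = read_plddt(pdb)
        from_json = read_plddt(tmp_path / "m.json", mode="json")
        assert np.allclose(from_pdb.values, from_json.values)

    def test_missing_residue_reported(self, tmp_path):
        path = tmp_path / "m.pdb"
        lines = []
        for i in [1, 2, 3, 4, 6, 7]:
            lines.append(
                f"ATOM  {i:>5}  CA  ALA A{i:>4}    {0.0:8.3f}{0.0:8.3f}{float(i):8.3f}"
                f"{1.00:6.2f}{80.0:6.2f}           C"
            )
        path.write_text("\n".join(lines) + "\nEND\n")
        with pytest.raises(DataValidationError, match="5"):
            read_plddt(path)

    def test_out_of_range_rejected(self, tmp_path):
        (tmp_path / "m.json").write_text(json.dumps([50.0, 120.0]))
        with pytest.raises(DataValidationError):
            read_plddt(tmp_path / "m.json", mode="json")


class TestDomainMapAndDataset:
    def test_topology_must_cover(self, tmp_path):
        path = tmp_path / "d.tsv"
        path.write_text(
            "start\tend\tlabel\ttrack\tflags\n1\t5\tcytoplasmic\ttopology\t\n"
        )
        with pytest.raises(DataValidationError, match="uncovered"):
            read_domain_map(path, length=10)

    def test_roundtrip_fixture(self, fixture_dir, gene):
        dm = read_domain_map(fixture_dir / "domains.tsv", gene.preset.length)
        assert dm.topology_at(1) == "cytoplasmic"
        label, flags = dm.domain_at(292)
        assert "selectivity_filter" in flags

    def test_labeled_dataset_binarization(self, fixture_dir):
        data = read_labeled_dataset(fixture_dir / "labels_pathogenicity.csv")
        assert set(data["label"]) == {0, 1}
        sev = read_labeled_dataset(fixture_dir / "labels_severity.csv", task="severity")
        assert set(sev["label"]) <= {"benign", "benign/severe", "severe"}

    def test_unknown_label_rejected(self, tmp_path):
        path = tmp_path / "d.csv"
        path.write_text("variant,label,split\nG2E,weird,train\n")
        with pytest.raises(DataValidationError):
            read_labeled_dataset(path)
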