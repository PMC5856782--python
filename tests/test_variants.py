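"""Variant table I/O, substitution classes, densities, Venn partition,
coding-effect classification."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from altipop.variants import (
    MISSING,
    PopulationDesign,
    TranscriptAnnotation,
    VariantTable,
    classify_coding_effect,
    classify_substitution,
    coding_effect_table,
    private_shared_sets,
    read_vcf,
    snp_density,
    spectrum_counts,
    ts_tv_ratio,
    write_vcf,
)


def _tiny_table():
    return VariantTable(
        ["T1", "T1", "T2"], [5, 9, 3], ["A", "C", "G"], ["G", "T", "C"],
        np.array([[0, 1, 2], [1, 1, 0], [2, MISSING, 0]], dtype=np.int8),
        ["s1", "s2", "s3"],
    )


class TestVcfRoundTrip:
    def test_round_trip_identity(self, tmp_path):
        t = _tiny_table()
        path = str(tmp_path / "t.vcf")
        write_vcf(t, path, contig_lengths={"T1": 100, "T2": 50})
        back, skipped = read_vcf(path)
        assert skipped == 0
        assert back == t

    def test_empty_body(self, tmp_path):
        path = tmp_path / "empty.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
        )
        table, skipped = read_vcf(str(path))
        assert table.n_sites == 0 and skipped == 0

    def test_triallelic_site_skipped(self, tmp_path):
        path = tmp_path / "tri.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=T1,length=100>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
            "T1\t5\t.\tA\tG,T\t.\t.\t.\tGT\t0/1\n"
            "T1\t9\t.\tC\tT\t.\t.\t.\tGT\t1/1\n"
        )
        table, skipped = read_vcf(str(path))
        assert skipped == 1
        assert table.n_sites == 1
        assert table.genotypes[0, 0] == 2

    def test_missing_gt_format_rejected(self, tmp_path):
        path = tmp_path / "nogt.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        )
        with pytest.raises(ValueError, match="GT"):
            read_vcf(str(path))


class TestInvariants:
    def test_ref_equals_alt_rejected(self):
        with pytest.raises(ValueError):
            VariantTable(["T1"], [1], ["A"], ["A"], np.zeros((1, 1), np.int8), ["s1"])

    def test_duplicate_position_rejected(self):
        with pytest.raises(ValueError):
            VariantTable(
                ["T1", "T1"], [1, 1], ["A", "C"], ["G", "T"],
                np.zeros((2, 1), np.int8), ["s1"],
            )

    def test_dosage_domain_rejected(self):
        with pytest.raises(ValueError):
            VariantTable(["T1"], [1], ["A"], ["G"], np.full((1, 1), 3, np.int8), ["s1"])


class TestSubstitutions:
    @pytest.mark.parametrize(
        "ref,alt,kind",
        [("A", "G", "transition"), ("G", "A", "transition"), ("C", "T", "transition"),
         ("T", "C", "transition"), ("G", "C", "transversion"), ("A", "T", "transversion"),
         ("A", "C", "transversion")],
    )
    def test_classification(self, ref, alt, kind):
        assert classify_substitution(ref, alt) == kind

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError):
            classify_substitution("N", "A")

    def test_ts_tv_arithmetic(self):
        # 27 A->G transitions and 10 A->C transversions: ratio 2.7
        n = 37
        table = VariantTable(
            ["T1"] * n, list(range(1, n + 1)), ["A"] * n,
            ["G"] * 27 + ["C"] * 10,
            np.ones((n, 2), np.int8), ["s1", "s2"],
        )
        assert ts_tv_ratio(table) == pytest.approx(2.7)

    def test_spectrum_sums_to_table_size(self, default_dataset):
        table = default_dataset["table"]
        spec = spectrum_counts(table)
        assert int(spec["all"].sum()) == table.n_sites


def _one_pop_design():
    return PopulationDesign(("P",), {"s1": "P", "s2": "P", "s3": "P"})


class TestDensity:
    def _annotation(self, covered):
        return TranscriptAnnotation(pd.DataFrame([dict(
            transcript_id="T1", length=covered, cds_start=0, cds_end=0, frame=0,
            utr5_start=0, utr5_end=0, utr3_start=0, utr3_end=0, covered_bp=covered,
        )]))

    def test_simple_arithmetic(self):
        # 10 segregating sites over 1 Mb -> 10.0/Mb
        n = 10
        table = VariantTable(
            ["T1"] * n, list(range(1, n + 1)), ["A"] * n, ["G"] * n,
            np.tile([0, 1, 2], (n, 1)).astype(np.int8), ["s1", "s2", "s3"],
        )
        dens = snp_density(table, _one_pop_design(), self._annotation(1_000_000))
        assert dens.density_per_mb.iloc[0] == pytest.approx(10.0)

    def test_no_segregating_sites(self):
        table = VariantTable(
            ["T1"], [1], ["A"], ["G"],
            np.array([[2, 2, 2]], np.int8), ["s1", "s2", "s3"],
        )
        dens = snp_density(table, _one_pop_design(), self._annotation(1_000_000))
        assert dens.density_per_mb.iloc[0] == 0.0

    def test_zero_covered_length_rejected(self, default_dataset):
        ann = default_dataset["annotation"]
        broken = TranscriptAnnotation(ann.table.assign(covered_bp=0), ann.sequences)
        with pytest.raises(ValueError, match="covered"):
            snp_density(default_dataset["table"], default_dataset["design"], broken)

    def test_multiplier_reflected_in_density_ratio(self, default_dataset):
        dens = snp_density(
            default_dataset["table"], default_dataset["design"], default_dataset["annotation"]
        ).set_index("population").density_per_mb
        assert 1.5 <= dens["H"] / dens["L"] <= 2.1


class TestVennPartition:
    def test_private_site_definition(self):
        design = PopulationDesign(
            ("L", "H"), {"l1": "L", "l2": "L", "h1": "H", "h2": "H"}
        )
        table = VariantTable(
            ["T1"], [1], ["A"], ["G"],
            np.array([[0, 0, 1, 2]], np.int8), ["l1", "l2", "h1", "h2"],
        )
        assert private_shared_sets(table, design) == {"H": 1}

    def test_triple_intersection_only(self, default_dataset):
        table, design = default_dataset["table"], default_dataset["design"]
        idx = design.indices(table)
        counts = private_shared_sets(table, design)
        # a site present everywhere lands only in the full-intersection region
        everywhere = np.ones(table.n_sites, bool)
        for lab in design.labels:
            everywhere &= table.present_mask(idx[lab])
        assert counts.get("H+L+M", 0) == int(everywhere.sum())

    def test_regions_partition_total(self, default_dataset):
        counts = private_shared_sets(default_dataset["table"], default_dataset["design"])
        assert sum(counts.values()) == default_dataset["table"].n_sites


class TestCodingEffect:
    @pytest.fixture()
    def annotation(self):
        #       1-6 utr5, 7-15 CDS (3 codons), 16-20 utr3
        seq = "AAAAAACTTATGTAAGGGGG"
        table = pd.DataFrame([dict(
            transcript_id="T1", length=20, cds_start=7, cds_end=15, frame=0,
            utr5_start=1, utr5_end=6, utr3_start=16, utr3_end=20, covered_bp=20,
        )])
        return TranscriptAnnotation(table, {"T1": seq})

    def test_synonymous_third_position(self, annotation):
        # CTT -> CTC, both Leu
        effect, stop = classify_coding_effect("T1", 9, "T", "C", annotation)
        assert effect == "synonymous" and not stop

    def test_non_synonymous_start_codon(self, annotation):
        # ATG -> ATA, Met -> Ile
        effect, stop = classify_coding_effect("T1", 12, "G", "A", annotation)
        assert effect == "non-synonymous" and not stop

    def test_stop_loss_flagged(self, annotation):
        # TAA -> CAA, stop -> Gln
        effect, stop = classify_coding_effect("T1", 13, "T", "C", annotation)
        assert effect == "non-synonymous" and stop

    def test_utr_lookup(self, annotation):
        assert classify_coding_effect("T1", 17, "G", "A", annotation)[0] == "utr3"
        assert classify_coding_effect("T1", 3, "A", "T", annotation)[0] == "utr5"

    def test_agrees_with_full_cds_retranslation(self, rng):
        """Brute-force oracle: retranslate the whole CDS with the SNP applied."""
        for _ in range(20):
            L = int(rng.integers(30, 90))
            cds_len = 3 * int(rng.integers(5, (L - 6) // 3))
            seq = "".join(rng.choice(list("ACGT"), size=L))
            ann = TranscriptAnnotation(
                pd.DataFrame([dict(
                    transcript_id="T1", length=L, cds_start=4, cds_end=3 + cds_len,
                    frame=0, utr5_start=1, utr5_end=3,
                    utr3_start=4 + cds_len if 4 + cds_len <= L else 0,
                    utr3_end=L if 4 + cds_len <= L else 0, covered_bp=L,
                )]),
                {"T1": seq},
            )
            pos = int(rng.integers(4, 4 + cds_len))
            ref = seq[pos - 1]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            effect, _ = classify_coding_effect("T1", pos, ref, alt, ann)
            cds = seq[3 : 3 + cds_len]
            mutated = cds[: pos - 4] + alt + cds[pos - 3 :]
            same = str(Seq(cds).translate()) == str(Seq(mutated).translate())
            assert effect == ("synonymous" if same else "non-synonymous")

    def test_effect_table_covers_all_sites(self, default_dataset):
        tab = coding_effect_table(
            default_dataset["table"], default_dataset["annotation"], default_dataset["design"]
        )
        assert len(tab) == default_dataset["table"].n_sites
        assert set(tab.effect) <= {"synonymous", "non-synonymous", "utr5", "utr3", "noncoding"}
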