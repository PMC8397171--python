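import math
from dataclasses import replace

import pytest

import mitolepi as ml
from mitolepi.composition import (
    base_composition,
    codon_usage,
    composition_table,
    extract_codons,
    usage_panel,
)
from mitolepi.genome import PCG_ORDER

from conftest import SIM_SEED, tiny_record


def handmade_record(interiors: dict) -> ml.MitogenomeRecord:
    """13 abutting F-strand PCGs, each ATG + given codons + TAA (cox1 starts
    CGA); codon counts are therefore known by hand."""
    feats, chunks, pos = [], [], 1
    for gene in PCG_ORDER:
        start = "CGA" if gene == "cox1" else "ATG"
        body = start + "".join(interiors.get(gene, [])) + "TAA"
        feats.append(
            ml.GeneFeature(name=gene, strand="F", start=pos, end=pos + len(body) - 1,
                           start_codon=start, stop_codon="TAA")
        )
        chunks.append(body)
        pos += len(body)
    seq = "".join(chunks)
    ann = ml.MitogenomeAnnotation(species="handmade", genome_length=len(seq), features=feats)
    return ml.MitogenomeRecord(annotation=ann, sequence=seq)


class TestBaseComposition:
    def test_homopolymer(self):
        row = base_composition(tiny_record("AAAA"), ["whole"])[0]
        assert row.pct_a == 100 and row.pct_at == 100 and row.at_skew == 1

    def test_hand_counted_pentamer(self):
        row = base_composition(tiny_record("ATAGA"), ["whole"])[0]
        assert (row.pct_a, row.pct_t, row.pct_g, row.pct_c) == (60, 20, 20, 0)

    def test_n_bases_excluded_from_denominator(self):
        row = base_composition(tiny_record("AANN"), ["whole"])[0]
        assert row.count_n == 2 and row.pct_a == 100

    def test_synthetic_whole_genome_hits_at_target(self, sim):
        rec, truth = sim
        row = base_composition(rec, ["whole"])[0]
        assert abs(row.pct_at - 100 * truth.at_targets["whole"]) < 1.0

    def test_region_counts_match_generator_bookkeeping(self, sim):
        rec, truth = sim
        for region in ("whole", "control_region"):
            row = base_composition(rec, [region])[0]
            expected = truth.base_counts[region]
            assert (row.count_a, row.count_t, row.count_g, row.count_c) == (
                expected["A"], expected["T"], expected["G"], expected["C"])

    def test_percentages_sum_to_100_after_rounding(self, sim):
        rec, _ = sim
        df = composition_table(base_composition(rec))
        for _, r in df.iterrows():
            assert abs(r["A%"] + r["T%"] + r["G%"] + r["C%"] - 100) <= 0.2

    def test_gene_rows_use_the_coding_strand(self, sim):
        rec, _ = sim
        row = base_composition(rec, ["nad1"])[0]  # R-strand gene
        sense = ml.feature_sequence(rec, "nad1")
        assert row.count_a == sense.count("A")

    def test_empty_and_unknown_regions_raise(self, sim):
        rec, _ = sim
        with pytest.raises(ValueError):
            base_composition(rec, ["not-a-gene"])


class TestCodonExtraction:
    def test_minimal_open_reading_frame(self):
        ext = extract_codons(tiny_record("ATGTAA", name="nad2"), "nad2")
        assert ext.codons == ("ATG",)
        assert ext.start_codon == "ATG" and ext.stop_codon == "TAA"
        assert not ext.truncated_stop and not ext.noncanonical_start

    def test_truncated_stop_detected(self):
        ext = extract_codons(tiny_record("ATGAAAT", name="nad2"), "nad2")
        assert ext.codons == ("ATG", "AAA") and ext.stop_codon == "T"
        assert ext.truncated_stop

    def test_internal_stop_reported_not_raised(self):
        ext = extract_codons(tiny_record("ATGTAAAAATAA", name="nad2"), "nad2")
        assert ext.internal_stops == (1,)

    @pytest.mark.parametrize("gene,n_triplets", [("cox2", 226), ("nad4", 446)])
    def test_polyadenylation_completed_genes(self, sim, gene, n_triplets):
        rec, _ = sim
        ext = extract_codons(rec, gene)
        assert len(ext.codons) == n_triplets
        assert ext.stop_codon == "T" and ext.truncated_stop

    def test_triplet_count_arithmetic_for_every_pcg(self, sim):
        rec, _ = sim
        for gene in PCG_ORDER:
            f = rec.annotation.feature(gene)
            ext = extract_codons(rec, gene)
            full_stop = 1 if (not ext.truncated_stop and ext.stop_codon) else 0
            assert len(ext.codons) + full_stop == f.size // 3
            assert ext.truncated_stop == (f.size % 3 != 0)

    def test_cga_initiator_flagged_only_outside_cox1(self, sim):
        rec, _ = sim
        assert not extract_codons(rec, "cox1").noncanonical_start
        ext = extract_codons(tiny_record("CGAAAATAA", name="nad2"), "nad2")
        assert ext.noncanonical_start

    def test_too_short_gene_raises(self):
        with pytest.raises(ValueError, match="too short"):
            extract_codons(tiny_record("ATGTA", name="nad2"), "nad2")


class TestCodonUsage:
    def test_forced_family_counts_give_forced_rscu(self):
        # Leu2 = {UUA, UUG} with counts 9 and 1 -> RSCU 1.8 / 0.2
        interiors = {
            "nad2": ["TTA"] * 5 + ["TTT", "TTC"],
            "cox1": ["TTA"] * 4 + ["TTG", "TTT", "TTC"],
        }
        table = codon_usage([handmade_record(interiors)])["handmade"]
        assert table.rscu["UUA"] == pytest.approx(1.8)
        assert table.rscu["UUG"] == pytest.approx(0.2)
        # uniform family -> RSCU 1 everywhere in it
        assert table.rscu["UUU"] == pytest.approx(1.0)
        assert table.rscu["UUC"] == pytest.approx(1.0)

    def test_hand_counted_totals_and_start_codon_handling(self):
        interiors = {"nad2": ["GGA", "GGA"]}
        table = codon_usage([handmade_record(interiors)])["handmade"]
        # 13 start codons + 2 interiors; stops excluded by default
        assert table.total_codons == 15
        assert table.counts["AUG"] == 12 and table.counts["CGA"] == 1
        assert table.counts["GGA"] == 2
        # the CGA initiator may not masquerade as arginine
        assert table.excluded_from_families == {"CGA": 1}
        assert table.rscu["CGA"] is None  # no real Arg usage at all

    def test_unused_codons_listed(self):
        table = codon_usage([handmade_record({"nad2": ["GGA"]})])["handmade"]
        assert "UCG" in table.unused_codons()
        assert "GGA" not in table.unused_codons()

    def test_synthetic_counts_recovered_exactly(self, sim):
        rec, truth = sim
        table = codon_usage([rec])[rec.annotation.species]
        assert table.counts == truth.codon_counts
        assert table.total_codons == truth.total_codons

    def test_family_rscu_sums_to_family_size(self, sim, code):
        rec, _ = sim
        table = codon_usage([rec])[rec.annotation.species]
        for fam, codons in code.families.items():
            values = [table.rscu[c.replace("T", "U")] for c in codons]
            if all(v is not None for v in values):
                assert math.isclose(sum(values), len(codons), rel_tol=1e-12)

    def test_cdspt_sums_to_1000_up_to_excluded_starts(self, sim):
        rec, _ = sim
        table = codon_usage([rec])[rec.annotation.species]
        excluded = sum(table.excluded_from_families.values())
        expected = 1000.0 * (table.total_codons - excluded) / table.total_codons
        assert math.isclose(sum(table.cdspt.values()), expected, abs_tol=1e-9)
        assert abs(sum(round(v, 1) for v in table.cdspt.values()) - 1000) <= 0.5

    def test_include_stop_toggle_adds_full_stops_only(self, sim):
        rec, _ = sim
        base = codon_usage([rec])[rec.annotation.species]
        with_stop = codon_usage([rec], include_stop=True)[rec.annotation.species]
        n_full_stops = sum(
            1 for g in PCG_ORDER
            if not extract_codons(rec, g).truncated_stop
        )
        assert with_stop.total_codons == base.total_codons + n_full_stops

    def test_missing_pcg_is_an_error(self, sim):
        rec, _ = sim
        ann = rec.annotation
        pruned = ml.MitogenomeAnnotation(
            species=ann.species, genome_length=ann.genome_length,
            features=[f for f in ann.features if f.name != "nad6"],
        )
        with pytest.raises(ValueError, match="nad6"):
            codon_usage([ml.MitogenomeRecord(annotation=pruned, sequence=rec.sequence)])


class TestUsagePanel:
    def test_single_species_matrix_equals_its_rscu(self, sim):
        rec, _ = sim
        table = codon_usage([rec])[rec.annotation.species]
        panel = usage_panel([table])
        col = panel.rscu_matrix[rec.annotation.species]
        for codon, value in table.rscu.items():
            got = col.loc[codon]
            assert (value is None and math.isnan(got)) or got == pytest.approx(value)

    def test_identical_counts_give_identical_columns(self):
        tpl = ml.default_template()
        rec_a, _ = ml.simulate_mitogenome(tpl, seed=SIM_SEED)
        tpl_b = replace(tpl, species="twin")
        rec_b, _ = ml.simulate_mitogenome(tpl_b, seed=SIM_SEED)
        tables = list(codon_usage([rec_a]).values()) + list(codon_usage([rec_b]).values())
        panel = usage_panel(tables)
        a, b = panel.rscu_matrix.columns
        assert panel.rscu_matrix[a].equals(panel.rscu_matrix[b])
        assert panel.unused[a] == panel.unused[b]

    def test_duplicate_labels_rejected(self, sim):
        rec, _ = sim
        table = codon_usage([rec])[rec.annotation.species]
        with pytest.raises(ValueError, match="duplicate"):
            usage_panel([table, table])

    def test_family_ranking_is_sorted_by_cdspt(self, sim):
        rec, _ = sim
        table = codon_usage([rec])[rec.annotation.species]
        ranking = usage_panel([table]).family_ranking[rec.annotation.species]
        values = [v for _, v in ranking]
        assert values == sorted(values, reverse=True)
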