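"""Long-read QC: extraction, cargo classification, whitelisting."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nicrseq import IcrLibraryConfig, simulate_icr_library
from nicrseq.barcode import reverse_complement
from nicrseq.qc import (
    ClassifyParams,
    ExtractionError,
    aggregate_and_whitelist,
    associate_reads,
    classify_cargo,
    classify_read_table,
    extract_icr,
    library_report,
    whitelists_by_set,
)


def _read(layout, barcode, cargo):
    return layout.upstream_anchor + barcode + layout.downstream_anchor + cargo


def _brute_force_anchor(seq, anchor, max_mm):
    """Independent sliding-window Hamming scan (leftmost acceptable hit)."""
    for i in range(len(seq) - len(anchor) + 1):
        if sum(a != b for a, b in zip(seq[i : i + len(anchor)], anchor)) <= max_mm:
            return i
    return -1


class TestExtract:
    def test_constructed_read(self, codebook, layout):
        spec = codebook.spec("RAD1")
        bc = spec.hardcode + "GATTACAGAT"
        assoc = extract_icr(_read(layout, bc, spec.reference_seq), layout, 2, "r1")
        assert assoc.icr.sequence == bc
        assert assoc.cargo_seq == spec.reference_seq

    def test_reverse_complement_read(self, codebook, layout):
        spec = codebook.spec("ERCC1")
        bc = spec.hardcode + "GATTACAGAT"
        fwd = _read(layout, bc, spec.reference_seq)
        assoc = extract_icr(reverse_complement(fwd), layout, 2)
        assert assoc.icr.sequence == bc
        assert assoc.cargo_seq == spec.reference_seq

    def test_anchor_beyond_tolerance_dropped(self, codebook, layout):
        spec = codebook.spec("RAD10")
        bc = spec.hardcode + "GATTACAGAT"
        read = _read(layout, bc, spec.reference_seq)
        # 3 substitutions into the upstream anchor at tolerance 2
        anchor = layout.upstream_anchor
        mutated = "".join(
            ("A" if c != "A" else "C") if i in (2, 7, 12) else c
            for i, c in enumerate(anchor)
        )
        bad = mutated + read[len(anchor):]
        assert _brute_force_anchor(bad, anchor, 2) != 0
        with pytest.raises(ExtractionError):
            extract_icr(bad, layout, anchor_mismatch=2)
        # the brute-force scan agrees there is no acceptable hit on either strand
        assert _brute_force_anchor(bad, anchor, 2) == -1
        assert _brute_force_anchor(reverse_complement(bad), anchor, 2) == -1

    def test_associate_reads_counts_drops(self, layout):
        good = _read(layout, "A" * 14, "C" * 200)
        reads = [("ok", good), ("junk", "ACGT" * 30)]
        assocs, drops = associate_reads(reads, layout, 2)
        assert len(assocs) == 1
        assert drops["no_upstream_anchor"] == 1


class TestClassify:
    def test_exact_reference_is_correct(self, codebook):
        spec = codebook.spec("RAD14")
        cls, detail = classify_cargo(spec.reference_seq, spec, codebook)
        assert cls == "correct"

    def test_short_insert_is_primer_dimer(self, codebook):
        rng = np.random.default_rng(0)
        insert = "".join(rng.choice(list("ACGT"), 60))
        cls, detail = classify_cargo(insert, codebook.spec("RAD1"), codebook)
        assert cls == "primer_dimer" and detail["insert_len"] == 60

    def test_wrong_gene_is_misassociated(self, codebook):
        """The canonical mix-up: one cargo's reference under another cargo's
        hardcode.  Cross-checked against a Biopython global-alignment
        best-match search over all nine references."""
        from Bio import Align

        rad10 = codebook.spec("RAD10").reference_seq
        expected = codebook.spec("ERCC1")
        cls, detail = classify_cargo(rad10, expected, codebook)
        assert cls == "misassociated" and detail["best"] == "RAD10"

        aligner = Align.PairwiseAligner(
            mode="global", match_score=1, mismatch_score=-1,
            open_gap_score=-2, extend_gap_score=-2,
        )
        scores = {s.name: aligner.score(rad10, s.reference_seq) for s in codebook}
        assert max(scores, key=scores.get) == "RAD10"

    def test_mutation_positions_and_primer_flag(self, codebook):
        spec = codebook.spec("XPA")
        ref = spec.reference_seq
        edge = ref[:5] + ("A" if ref[5] != "A" else "C") + ref[6:]
        cls, detail = classify_cargo(edge, spec, codebook)
        assert cls == "mutant_snp_indel" and detail["primer_region_only"]

        mid = ref[:150] + ("A" if ref[150] != "A" else "C") + ref[151:]
        cls, detail = classify_cargo(mid, spec, codebook)
        assert cls == "mutant_snp_indel" and not detail["primer_region_only"]
        ops = [(op, pos) for op, pos, _ in detail["variants"]]
        assert ops == [("X", 150)]

    def test_unrelated_sequence_unclassifiable(self, codebook):
        rng = np.random.default_rng(1)
        junk = "".join(rng.choice(list("ACGT"), 300))
        cls, _ = classify_cargo(junk, codebook.spec("RAD1"), codebook)
        assert cls == "unclassifiable"


def _mk_read_rows(barcode, cargo, classes):
    return [
        {
            "read_id": f"r{i}",
            "barcode": barcode,
            "expected_cargo": cargo,
            "read_class": cls,
            "primer_region_only": False,
            "assigned_cargo": cargo if cls in ("correct", "mutant_snp_indel") else "",
        }
        for i, cls in enumerate(classes)
    ]


class TestAggregate:
    def test_below_read_threshold_excluded(self):
        table = pd.DataFrame(_mk_read_rows("A" * 14, "RAD1", ["correct"] * 9))
        agg, wl = aggregate_and_whitelist(table, min_reads=10)
        assert agg.empty and wl == {}

    def test_correct_plus_primer_dimer_is_conflicting(self):
        rows = _mk_read_rows("A" * 14, "RAD1", ["correct"] * 12 + ["primer_dimer"])
        agg, wl = aggregate_and_whitelist(pd.DataFrame(rows), min_reads=10)
        assert agg["class"].tolist() == ["conflicting"]
        assert wl == {}

    def test_whitelist_matches_truth_exactly(self, clean_libraries, codebook, layout):
        """On error-free data the whitelist equals the truth's
        correct-or-primer-edge-mutant set, restricted to barcodes meeting the
        read threshold."""
        for name, (reads, truth) in clean_libraries.items():
            assocs, drops = associate_reads(reads, layout, 2)
            assert not drops
            read_table = classify_read_table(assocs, codebook)
            agg, wl = aggregate_and_whitelist(read_table, min_reads=10)
            eligible = truth[truth["n_reads"] >= 10]
            expected = set(
                eligible.loc[
                    (eligible["true_class"] == "correct")
                    | (
                        (eligible["true_class"] == "mutant_snp_indel")
                        & eligible["primer_region_only"]
                    ),
                    "barcode",
                ]
            )
            assert wl.get(name, set()) == expected

    def test_order_and_shard_invariance(self, clean_libraries, codebook, layout):
        reads, _ = clean_libraries["RAD10"]
        assocs, _ = associate_reads(reads, layout, 2)
        table = classify_read_table(assocs, codebook)
        shuffled = table.sample(frac=1.0, random_state=4).reset_index(drop=True)
        a1, w1 = aggregate_and_whitelist(table, min_reads=10)
        a2, w2 = aggregate_and_whitelist(shuffled, min_reads=10)
        pd.testing.assert_frame_equal(
            a1.sort_values("barcode").reset_index(drop=True),
            a2.sort_values("barcode").reset_index(drop=True),
        )
        assert w1 == w2

    def test_whitelist_subset_of_kept_and_disjoint_from_conflicting(
        self, clean_libraries, codebook, layout
    ):
        reads, _ = clean_libraries["RAD1"]
        assocs, _ = associate_reads(reads, layout, 2)
        agg, wl = aggregate_and_whitelist(classify_read_table(assocs, codebook), 10)
        kept = set(agg["barcode"])
        conflicting = set(agg.loc[agg["class"] == "conflicting", "barcode"])
        listed = set().union(*wl.values()) if wl else set()
        assert listed <= kept
        assert not (listed & conflicting)

    def test_majority_vote_tolerates_sequencing_errors(self, codebook, layout):
        """With a low per-base error rate and read depth comparable to the
        long-read QC coverage, majority voting keeps per-barcode
        classification accuracy at >= 99%."""
        cfg = IcrLibraryConfig(
            n_barcodes_per_cargo=50,
            reads_per_barcode=40.0,
            per_base_error=0.001,
            seed=21,
        )
        spec = codebook.spec("RAD1")
        reads, truth = simulate_icr_library(spec, codebook, cfg, layout)
        assocs, _ = associate_reads(reads, layout, 2)
        agg, _ = aggregate_and_whitelist(
            classify_read_table(assocs, codebook), min_reads=10
        )
        merged = agg.merge(truth, on="barcode")
        merged = merged[merged["n_reads_y"] >= 10]
        accuracy = (merged["class"] == merged["true_class"]).mean()
        assert accuracy >= 0.99


class TestReport:
    def test_empty_table(self):
        report = library_report(pd.DataFrame(columns=[
            "barcode", "expected_cargo", "n_reads", "class",
            "primer_region_only", "assigned_cargo"]))
        assert report["summary"].empty

    def test_percentages_sum_to_100(self, clean_libraries, codebook, layout):
        reads, _ = clean_libraries["ERCC4"]
        assocs, _ = associate_reads(reads, layout, 2)
        agg, _ = aggregate_and_whitelist(classify_read_table(assocs, codebook), 10)
        summary = library_report(agg)["summary"]
        pct_cols = [c for c in summary.columns if c.startswith("pct_")]
        assert np.allclose(summary[pct_cols].sum(axis=1), 100.0)

    def test_class_fractions_within_binomial_ci(self, codebook, layout):
        rates = {
            "correct": 0.9,
            "primer_dimer": 0.05,
            "misassociated": 0.03,
            "mutant_snp_indel": 0.02,
        }
        cfg = IcrLibraryConfig(
            n_barcodes_per_cargo=400, class_rates=rates,
            reads_per_barcode=12.0, per_base_error=0.0, seed=31,
        )
        spec = codebook.spec("RAD14")
        reads, _ = simulate_icr_library(spec, codebook, cfg, layout)
        assocs, _ = associate_reads(reads, layout, 2)
        agg, _ = aggregate_and_whitelist(classify_read_table(assocs, codebook), 5)
        summary = library_report(agg)["summary"]
        n = int(summary.loc["RAD14", "n_barcodes"])
        for cls, p in rates.items():
            k = round(summary.loc["RAD14", f"pct_{cls}"] / 100 * n)
            lo = stats.binom.ppf(0.005, n, p)
            hi = stats.binom.ppf(0.995, n, p)
            assert lo <= k <= hi, cls

    def test_whitelists_by_set_unions_cargos(self, codebook):
        wl = {"RAD1": {"A" * 14}, "ERCC4": {"C" * 14}, "RAD10": {"G" * 14}}
        by_set = whitelists_by_set(wl, codebook)
        assert by_set[1] == {"A" * 14, "C" * 14}
        assert by_set[2] == {"G" * 14}
        assert by_set[3] == set()
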