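"""Study-table filtering rules and distance derivation."""

import numpy as np
import pandas as pd
import pytest

from cistrans.preprocess import (
    compute_distances,
    filter_eqtl_zscore,
    filter_intrachromosomal_primary,
    filter_metabolite_single_gene,
    load_study_table,
)


def rec(trait, vchrom, vpos, gchrom, gtss, strength, rank=None, dist=None, pvalue=None):
    return dict(trait=trait, variant_chrom=vchrom, variant_pos=vpos,
                gene_chrom=gchrom, gene_tss=gtss, strength=strength,
                rank=rank, dist=dist, pvalue=pvalue)


@pytest.fixture
def toy_pqtl():
    # trait A has an interchromosomal hit stronger than its intrachromosomal
    # one; trait B has two intrachromosomal hits
    return pd.DataFrame([
        rec("A", "chr1", 100, "chr2", 5_000, strength=50.0),
        rec("A", "chr2", 900, "chr2", 5_000, strength=30.0),
        rec("B", "chr3", 10, "chr3", 500, strength=12.0),
        rec("B", "chr3", 400, "chr3", 500, strength=9.0),
        rec("C", "chr4", 77, "chr5", 200, strength=8.0),
    ])


class TestIntrachromosomalPrimary:
    def test_toy_table(self, toy_pqtl):
        kept, rejected = filter_intrachromosomal_primary(toy_pqtl)
        assert len(kept) == 2
        assert set(kept["trait"]) == {"A", "B"}
        assert kept.set_index("trait").loc["A", "variant_pos"] == 900
        assert kept.set_index("trait").loc["B", "variant_pos"] == 10
        # trait C has no intrachromosomal record at all
        assert (rejected.query("trait == 'C'")["reason"] == "interchromosomal").all()

    def test_multi_gene_trait_kept_via_chromosome_match(self):
        # a protein mapping to two genes: only the pairing whose gene shares
        # the variant's chromosome survives
        df = pd.DataFrame([
            rec("P", "chr7", 1000, "chr7", 9_000, strength=20.0),
            rec("P", "chr7", 1000, "chr11", 9_000, strength=20.0),
        ])
        kept, rejected = filter_intrachromosomal_primary(df)
        assert len(kept) == 1 and kept.iloc[0]["gene_chrom"] == "chr7"

    def test_rank_column_honoured(self):
        df = pd.DataFrame([
            rec("T", "chr1", 10, "chr1", 500, strength=5.0, rank="primary"),
            rec("T", "chr1", 999, "chr1", 500, strength=50.0, rank="secondary"),
        ])
        kept, _ = filter_intrachromosomal_primary(df)
        assert kept.iloc[0]["variant_pos"] == 10

    def test_matches_brute_force_groupby(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(200):
            trait = f"T{rng.integers(0, 40)}"
            c1, c2 = f"chr{rng.integers(1, 5)}", f"chr{rng.integers(1, 5)}"
            rows.append(rec(trait, c1, int(rng.integers(1, 10**6)),
                            c2, int(rng.integers(1, 10**6)),
                            strength=float(rng.uniform(1, 100))))
        df = pd.DataFrame(rows)
        kept, rejected = filter_intrachromosomal_primary(df)

        expected = {}
        for r in rows:
            if r["variant_chrom"] != r["gene_chrom"]:
                continue
            cur = expected.get(r["trait"])
            key = (-r["strength"], abs(r["variant_pos"] - r["gene_tss"]), r["variant_pos"])
            if cur is None or key < cur[0]:
                expected[r["trait"]] = (key, r)
        assert len(kept) == len(expected)
        for _, row in kept.iterrows():
            want = expected[row["trait"]][1]
            assert row["variant_pos"] == want["variant_pos"]
        # conservation: every input row is kept or rejected exactly once
        assert len(kept) + len(rejected) == len(df)

    def test_idempotent(self, toy_pqtl):
        once, _ = filter_intrachromosomal_primary(toy_pqtl)
        twice, rej = filter_intrachromosomal_primary(once)
        pd.testing.assert_frame_equal(
            once.reset_index(drop=True)[twice.columns], twice.reset_index(drop=True))
        assert len(rej) == 0


class TestEqtlZscore:
    def test_threshold_is_inclusive(self):
        df = pd.DataFrame([
            rec("G1", "chr1", 10, "chr1", 99, strength=5.4485),
            rec("G2", "chr1", 10, "chr1", 99, strength=5.4484),
            rec("G3", "chr1", 10, "chr1", 99, strength=-7.0),
        ])
        kept, rejected = filter_eqtl_zscore(df)
        assert set(kept["trait"]) == {"G1", "G3"}
        assert (rejected["reason"] == "below_z_threshold").sum() == 1

    def test_matches_manual_filter(self):
        z = [3.0, 5.0, 5.4485, 5.45, -5.4485, -5.4484, 6.0, 10.0, 0.0, -20.0]
        df = pd.DataFrame([rec(f"G{i}", "chr1", 10 + i, "chr1", 99, strength=s)
                           for i, s in enumerate(z)])
        kept, _ = filter_eqtl_zscore(df)
        manual = {f"G{i}" for i, s in enumerate(z) if abs(s) >= 5.4485}
        assert set(kept["trait"]) == manual

    def test_keeps_largest_absolute_z_per_gene(self):
        df = pd.DataFrame([
            rec("G", "chr1", 10, "chr1", 99, strength=6.0),
            rec("G", "chr1", 20, "chr1", 99, strength=-9.0),
        ])
        kept, _ = filter_eqtl_zscore(df)
        assert len(kept) == 1 and kept.iloc[0]["variant_pos"] == 20


class TestMetaboliteSingleGene:
    @pytest.fixture
    def gene_map(self):
        return pd.DataFrame([
            {"trait": "M1", "gene": "GA", "gene_chrom": "chr1", "gene_tss": 1000},
            {"trait": "M1", "gene": "GB", "gene_chrom": "chr1", "gene_tss": 9000},
            {"trait": "M1", "gene": "GC", "gene_chrom": "chr2", "gene_tss": 4000},
        ])

    def test_single_gene_per_chromosome_rule(self, gene_map):
        df = pd.DataFrame([
            rec("M1", "chr1", 500, None, None, strength=None, pvalue=1e-12),
            rec("M1", "chr2", 4500, None, None, strength=None, pvalue=1e-10),
        ])
        kept, rejected = filter_metabolite_single_gene(df, gene_map)
        # chr1 has two interacting genes -> ineligible; chr2 has exactly one
        assert len(kept) == 1 and kept.iloc[0]["variant_chrom"] == "chr2"
        assert (rejected["reason"] == "no_unique_interacting_gene").sum() == 1

    def test_pvalue_threshold_is_strict(self, gene_map):
        df = pd.DataFrame([rec("M1", "chr2", 4500, None, None,
                               strength=None, pvalue=5e-8)])
        kept, rejected = filter_metabolite_single_gene(df, gene_map)
        assert len(kept) == 0
        assert (rejected["reason"] == "above_p_threshold").sum() == 1

    def test_unknown_metabolite_dropped_with_reason(self, gene_map):
        df = pd.DataFrame([rec("M9", "chr2", 4500, None, None,
                               strength=None, pvalue=1e-12)])
        kept, rejected = filter_metabolite_single_gene(df, gene_map)
        assert len(kept) == 0
        assert (rejected["reason"] == "metabolite_not_in_map").all()

    def test_matches_brute_force_loop(self, gene_map):
        rng = np.random.default_rng(4)
        rows = [rec("M1", f"chr{rng.integers(1, 3)}", int(rng.integers(1, 10_000)),
                    None, None, strength=None, pvalue=float(10 ** -rng.uniform(4, 15)))
                for _ in range(30)]
        df = pd.DataFrame(rows)
        kept, _ = filter_metabolite_single_gene(df, gene_map)
        chr2 = [r for r in rows if r["variant_chrom"] == "chr2"]
        best = min(chr2, key=lambda r: (r["pvalue"], r["variant_pos"]))
        if best["pvalue"] < 5e-8:
            assert len(kept) == 1 and kept.iloc[0]["variant_pos"] == best["variant_pos"]
        else:
            assert len(kept) == 0


class TestComputeDistances:
    def test_positional_difference(self):
        df = pd.DataFrame([rec("T", "chr1", 1000, "chr1", 1500, strength=9.0)])
        out, rej = compute_distances(df)
        assert out.iloc[0]["dist"] == 500 and len(rej) == 0

    def test_precomputed_distance_passes_through(self):
        df = pd.DataFrame([rec("T", "chr1", None, "chr1", None, strength=9.0, dist=123)])
        out, _ = compute_distances(df)
        assert out.iloc[0]["dist"] == 123

    def test_mixed_records_match_manual_computation(self):
        df = pd.DataFrame([
            rec("T1", "chr1", 1000, "chr1", 1500, strength=1.0),
            rec("T2", "chr1", None, "chr1", None, strength=1.0, dist=77),
            rec("T3", "chr2", 9000, "chr2", 100, strength=1.0),
            rec("T4", "chr2", None, "chr2", None, strength=1.0),
        ])
        out, rej = compute_distances(df)
        assert list(out["dist"]) == [500, 77, 8900]
        assert len(rej) == 1 and rej.iloc[0]["reason"] == "no_distance_information"


class TestLoadStudyTable:
    def test_schema_mapping(self, tmp_path):
        src = tmp_path / "study.tsv"
        src.write_text("Protein\tSNPChrom\tSNPPos\n P1\tchr1\t100\n".replace(" ", ""))
        df = load_study_table(src, {"trait": "Protein", "variant_chrom": "SNPChrom",
                                    "variant_pos": "SNPPos"})
        assert list(df.columns) == ["trait", "variant_chrom", "variant_pos"]

    def test_missing_schema_column_rejected(self, tmp_path):
        src = tmp_path / "study.tsv"
        src.write_text("a\tb\n1\t2\n")
        with pytest.raises(ValueError):
            load_study_table(src, {"trait": "nope"})
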