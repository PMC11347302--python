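"""Generator correctness: determinism, dedup bookkeeping, ground truth."""

import math
from pathlib import Path

import numpy as np
import pytest

from pvsignal.contingency import build_contingency, term_table_frame
from pvsignal.disproportionality import ror_with_ci
from pvsignal.faers_io import ingest_quarters, load_drug_dictionary, load_pt_to_soc
from pvsignal.synthetic_data import (
    ConfigError,
    GroundTruth,
    SyntheticConfig,
    TARGET_DRUG,
    default_pt_dictionary,
    generate,
    realized_table,
    simulate_store,
)

FAST = dict(start_quarter="2023Q1", end_quarter="2023Q4")


class TestConfigValidation:
    def test_probability_vector_length_mismatch(self):
        with pytest.raises(ConfigError, match="length"):
            SyntheticConfig(background_pt_probs=(0.5, 0.5), **FAST).validate()

    def test_probabilities_must_sum_to_one(self):
        bad = tuple([0.5] + [0.01] * 99)
        with pytest.raises(ConfigError, match="sums to"):
            SyntheticConfig(background_pt_probs=bad, **FAST).validate()

    def test_unknown_injected_pt(self):
        with pytest.raises(ConfigError, match="not in pt_dictionary"):
            SyntheticConfig(injected_signals=(("NOPE", 2.0),), **FAST).validate()

    def test_rate_out_of_range(self):
        with pytest.raises(ConfigError, match="duplicate_rate"):
            SyntheticConfig(duplicate_rate=1.5, **FAST).validate()

    def test_empty_corpus_rejected(self):
        with pytest.raises(ConfigError, match="empty"):
            simulate_store(SyntheticConfig(n_reports=0, **FAST))


class TestDeterminism:
    def test_identical_seed_byte_identical_files(self, tmp_path):
        cfg = SyntheticConfig(n_reports=500, seed=9, **FAST)
        generate(cfg, tmp_path / "a")
        generate(cfg, tmp_path / "b")
        files_a = sorted((tmp_path / "a").iterdir())
        files_b = sorted((tmp_path / "b").iterdir())
        assert [f.name for f in files_a] == [f.name for f in files_b]
        for fa, fb in zip(files_a, files_b):
            assert fa.read_bytes() == fb.read_bytes()

    def test_different_seed_differs(self, tmp_path):
        a, _ = simulate_store(SyntheticConfig(n_reports=500, seed=1, **FAST))
        b, _ = simulate_store(SyntheticConfig(n_reports=500, seed=2, **FAST))
        assert not a.equals(b)


class TestDedupBookkeeping:
    def test_ingest_recovers_configured_case_count(self, tmp_path):
        cfg = SyntheticConfig(n_reports=1000, duplicate_rate=0.2, seed=4, **FAST)
        _, truth = generate(cfg, tmp_path)
        store = ingest_quarters(tmp_path, load_drug_dictionary(tmp_path / "drug_dict.tsv"))
        assert store.n_reports == 1000
        assert truth.n_duplicates == 200
        assert store.meta["n_raw_demo_rows"] == 1200

    def test_duplicates_clone_linked_rows(self, tmp_path):
        cfg = SyntheticConfig(n_reports=200, duplicate_rate=0.5, seed=4, **FAST)
        _, truth = generate(cfg, tmp_path)
        reac_lines = sum(
            len(p.read_text().splitlines()) - 1 for p in tmp_path.glob("REAC*.txt")
        )
        store = ingest_quarters(tmp_path, {})
        # duplicates re-emit their REAC rows, dedup removes them again
        assert reac_lines > len(store.report_pts)


class TestGroundTruth:
    def test_realized_equals_contingency_for_every_pt(self, tmp_path):
        cfg = SyntheticConfig(
            n_reports=800, injected_signals=(("PT_003", 6.0),), seed=13, **FAST
        )
        _, truth = generate(cfg, tmp_path)
        store = ingest_quarters(tmp_path, load_drug_dictionary(tmp_path / "drug_dict.tsv"))
        frame = term_table_frame(store, TARGET_DRUG)
        for pt in truth.pts:
            expected = realized_table(truth, pt)
            if expected.a == 0:
                assert pt not in frame.index
                continue
            row = frame.loc[pt]
            assert (row.a, row.b, row.c, row.d) == expected.as_tuple()

    def test_unknown_pt_lookup_error(self, small_store):
        _, truth = small_store
        with pytest.raises(KeyError):
            realized_table(truth, "PT_999")

    def test_round_trips_through_json(self, tmp_path, small_store):
        _, truth = small_store
        truth.to_json(tmp_path / "gt.json")
        again = GroundTruth.from_json(tmp_path / "gt.json")
        assert again == truth

    def test_injected_excess_beyond_binomial_null(self, small_store):
        """An injected rate ratio of 8 must push a far above its null expectation."""
        _, truth = small_store
        t = realized_table(truth, "PT_001")
        n_target = truth.n_target_reports
        p_null = (t.a + t.c) / truth.n_reports
        # binomial tail: mean + 4 sd under independence
        bound = n_target * p_null + 4 * math.sqrt(n_target * p_null * (1 - p_null))
        assert t.a > bound

    def test_null_config_tables_near_independence(self):
        store, truth = simulate_store(SyntheticConfig(n_reports=8000, seed=21, **FAST))
        rates = []
        for pt in truth.pts:
            t = realized_table(truth, pt)
            p_t = t.a / (t.a + t.b)
            p_b = t.c / (t.c + t.d)
            rates.append(p_t - p_b)
        # centered differences: no systematic excess in either arm
        assert abs(float(np.mean(rates))) < 0.003


class TestEmittedDictionaries:
    def test_pt_to_soc_covers_dictionary(self, tmp_path):
        cfg = SyntheticConfig(n_reports=100, seed=2, **FAST)
        generate(cfg, tmp_path)
        mapping = load_pt_to_soc(tmp_path / "pt_to_soc.tsv")
        assert mapping == dict(default_pt_dictionary())

    def test_target_variants_standardize_to_canonical(self, tmp_path):
        cfg = SyntheticConfig(n_reports=400, seed=2, **FAST)
        generate(cfg, tmp_path)
        store = ingest_quarters(tmp_path, load_drug_dictionary(tmp_path / "drug_dict.tsv"))
        ps = store.report_drugs[store.report_drugs["role"] == "PS"]
        target = ps[ps["drug_std"] == TARGET_DRUG]
        assert target["drug_raw"].str.upper().nunique() > 1  # several variants seen
        assert (target["drug_std"] == TARGET_DRUG).all()


def test_small_replicate_coverage_smoke():
    """ROR 95% CI covers an injected rate ratio of 5 in most small replicates."""
    hits = 0
    n_rep = 30
    for i in range(n_rep):
        cfg = SyntheticConfig(
            n_reports=20_000, injected_signals=(("PT_001", 5.0),), seed=3000 + i,
        )
        _, truth = simulate_store(cfg)
        _, lo, hi = ror_with_ci(realized_table(truth, "PT_001"))
        hits += lo <= 5.0 <= hi
    assert hits >= 0.8 * n_rep
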