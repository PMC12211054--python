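"""Contamination-removal protocol: boundaries, per-step recall, invariants."""

import itertools

import numpy as np
import pandas as pd
import pytest

from hepmicro import decontam as dc
from hepmicro import synthetic_data as sd


def make_records(rows):
    return pd.DataFrame(rows, columns=dc.RECORD_COLUMNS)


def rec(sample, name, reads, total, unique, lineage=None):
    return (sample, 1, name, "species", lineage or name, reads, total, unique)


@pytest.mark.parametrize("rl,kl,expected", [(100, 31, 70), (150, 35, 116),
                                            (50, 50, 1)])
def test_unique_kmer_threshold(rl, kl, expected):
    assert dc.unique_kmer_threshold(rl, kl) == expected


def test_threshold_rejects_long_kmer():
    with pytest.raises(ValueError):
        dc.unique_kmer_threshold(30, 31)


def test_step1_boundary_convention():
    records = make_records([rec("s1", "below", 10, 5000, 69),
                            rec("s1", "at", 10, 5000, 70)])
    kept, entries = dc.filter_low_unique_kmers(records, 100, 31)
    assert list(kept["name"]) == ["at"]
    assert entries[0]["taxon"] == "below"


def test_step2_boundary_convention():
    records = make_records([
        rec("s1", "above", 10, 51, 40),
        rec("s1", "below", 10, 49, 40),
        rec("s1", "at", 10, 50, 40),       # equality is removed
        rec("s1", "degenerate", 0, 0, 0),
    ])
    kept, _ = dc.filter_low_total_kmers(records, fold=5)
    assert list(kept["name"]) == ["above"]


def test_step3_comonotone_retained_constant_removed():
    rows = []
    for i in range(5):
        rows.append(rec(f"s{i}", "good", 10 + i, 100 + 10 * i, 50 + 5 * i))
        rows.append(rec(f"s{i}", "flat", 10 + i, 100 + 10 * i, 42))
    kept, entries = dc.filter_decorrelated(make_records(rows), alpha=0.05,
                                           min_samples=5)
    assert set(kept["name"]) == {"good"}
    reasons = {e["taxon"]: e["reason"] for e in entries}
    assert "undefined" in reasons["flat"]


def test_step3_insufficiency():
    rows = [rec(f"s{i}", "sparse", 10 + i, 100 + i, 50 + i) for i in range(3)]
    kept, entries = dc.filter_decorrelated(make_records(rows), min_samples=5)
    assert kept.empty
    assert entries[0]["step"] == "insufficiency"


def test_step4_inverse_depth_signature_removed():
    """A taxon with constant reads while depth varies 20x is flagged."""
    rng = np.random.default_rng(0)
    rows = []
    depths = np.geomspace(1e3, 2e4, 20)
    for i, d in enumerate(depths):
        rows.append(rec(f"s{i}", "anchor", int(d), int(d) * 200, 5000))
        rows.append(rec(f"s{i}", "kit", 50 + int(rng.integers(0, 10)),
                        60_000, 5000))
    kept, entries = dc.filter_contaminant_like(make_records(rows),
                                               depth_test=True)
    assert "kit" not in set(kept["name"])
    assert "anchor" in set(kept["name"])


def test_step4_disabled_is_identity():
    rows = [rec("s1", "a", 10, 100, 50)]
    kept, entries = dc.filter_contaminant_like(make_records(rows),
                                               depth_test=False)
    assert len(kept) == 1 and entries == []


def test_step5_blacklist_matches_lineage():
    rows = [
        rec("s1", "Bradyrhizobium sp. X", 10, 100, 50,
            "Proteobacteria;C;O;F;Bradyrhizobium;Bradyrhizobium sp. X"),
        rec("s1", "Innocent", 10, 100, 50, "Firmicutes;C;O;F;G;Innocent"),
    ]
    kept, entries = dc.filter_blacklist(make_records(rows), {"bradyrhizobium"})
    assert list(kept["name"]) == ["Innocent"]
    kept2, e2 = dc.filter_blacklist(make_records(rows), set())
    assert len(kept2) == 2 and e2 == []


def test_run_decontam_per_step_recall(taxon_reports):
    cfg, reports, meta, truth = taxon_reports
    counts, report = dc.run_decontam(reports, datasets=meta["dataset"])
    first = report.first_steps()
    by_class = {}
    for taxon, cls in truth.contaminant_taxa.items():
        by_class.setdefault(cls, []).append(first.get(taxon, "KEPT"))
    step_for = {"low_unique_kmers": "low_unique_kmers",
                "low_total_kmers": "low_total_kmers",
                "decorrelated": "decorrelated", "blacklist": "blacklist"}
    for cls, outcomes in by_class.items():
        recall = np.mean([o == step_for[cls] for o in outcomes])
        assert recall >= 0.75, (cls, outcomes)
    genuine = {t for df in reports.values() for t in df["name"]
               if t not in truth.contaminant_taxa}
    retention = len(set(report.retained) & genuine) / len(genuine)
    assert retention >= 0.9


def test_filters_partition_and_idempotence(taxon_reports):
    cfg, reports, meta, truth = taxon_reports
    counts, report = dc.run_decontam(reports, datasets=meta["dataset"])
    all_taxa = {t for df in reports.values() for t in df["name"]}
    removed = set(report.removed["taxon"])
    assert removed | set(report.retained) == all_taxa
    assert removed & set(report.retained) == set()
    # idempotence: rerunning on the cleaned records (with sequencing depth
    # still measured on the original report) removes nothing more
    long = dc._as_records(reports)
    depth = long.groupby("sample_id")["reads"].sum()
    survivors = long[long["name"].isin(report.retained)]
    counts2, report2 = dc.run_decontam(survivors, datasets=meta["dataset"],
                                       sample_depth=depth)
    assert set(report2.retained) == set(report.retained)


def test_order_stability_for_disjoint_signatures():
    """For taxa violating exactly one rule, filter order cannot matter."""
    rows = []
    rng = np.random.default_rng(1)
    for i in range(8):
        rows.append(rec(f"s{i}", "genuine", 20 + 5 * i, (20 + 5 * i) * 120,
                        (20 + 5 * i) * 100))
        rows.append(rec(f"s{i}", "lowuni", 30 + 5 * i, (30 + 5 * i) * 120, 10 + i))
        rows.append(rec(f"s{i}", "lowtot", 100 + 10 * i, (100 + 10 * i) * 3,
                        (100 + 10 * i) * 2))
        rows.append(rec(f"s{i}", "decor", 20 + 5 * i, (20 + 5 * i) * 120,
                        [500, 320, 410, 380, 290, 450, 300, 520][i]))
        rows.append(rec(f"s{i}", "kitgenus", 20 + 5 * i, (20 + 5 * i) * 120,
                        (20 + 5 * i) * 100,
                        "P;C;O;F;Delftia;kitgenus"))
    records = make_records(rows)
    black = {"delftia"}

    def apply_order(order):
        recs = records
        for step in order:
            if step == 1:
                recs, _ = dc.filter_low_unique_kmers(recs, 150, 31)
            elif step == 2:
                recs, _ = dc.filter_low_total_kmers(recs)
            elif step == 3:
                recs, _ = dc.filter_decorrelated(recs)
            elif step == 5:
                recs, _ = dc.filter_blacklist(recs, black)
        return set(recs["name"])

    results = {frozenset(apply_order(p))
               for p in itertools.permutations([1, 2, 3, 5])}
    assert len(results) == 1
    assert next(iter(results)) == frozenset({"genuine"})


def test_monotonicity_in_fold_and_alpha(taxon_reports):
    cfg, reports, meta, _ = taxon_reports
    loose, _ = dc.run_decontam(reports, fold=3, alpha=0.01,
                               datasets=meta["dataset"])
    tight, _ = dc.run_decontam(reports, fold=7, alpha=0.10,
                               datasets=meta["dataset"])
    assert set(tight.columns) <= set(loose.columns)


def test_empty_reports_error():
    with pytest.raises(ValueError):
        dc.run_decontam({})


def test_no_survivors_gives_empty_profile():
    rows = [rec(f"s{i}", "junk", 10, 20, 3) for i in range(6)]
    counts, report = dc.run_decontam(make_records(rows))
    assert counts.empty and report.retained == []


def test_read_report_roundtrip(tmp_path):
    df = make_records([rec("s1", "A", 5, 100, 60), rec("s1", "B", 7, 140, 80)])
    p = tmp_path / "s1.tsv"
    df.to_csv(p, sep="\t", index=False)
    back = dc.read_report(p)
    pd.testing.assert_frame_equal(back, df)
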