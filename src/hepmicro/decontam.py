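"""Five-step contamination removal for tissue metatranscriptome profiles.

Taxonomic classifications of microbial reads mined from tissue RNA-seq are
dominated by artifacts: spurious k-mer hits, reagent ("kitome")
contaminants and cross-sample bleed.  This module implements a stringent
five-step filtering protocol over per-sample classification reports that
carry, for each taxon, its read count, total k-mer count and unique
(distinct) k-mer count:

1. remove taxa whose unique k-mer count falls below
   ``read_length − kmer_length + 1`` — a single genuine read already
   contributes that many distinct k-mers;
2. remove taxa whose total k-mer count does not exceed five-fold their
   read count (random spurious hits rather than genuine coverage);
3. remove taxa whose read / total-k-mer / unique-k-mer statistics are not
   all significantly Spearman-correlated across the samples of each
   dataset (genuine organisms rise and fall coherently);
4. remove taxa whose relative abundance shows the inverse-depth frequency
   signature of reagent contamination (or matches a supplied reference
   contaminant profile);
5. remove taxa matching a published reagent-contaminant blacklist, by
   name or by any lineage ancestor.

Steps 1–2 act per (taxon, sample) record; steps 3–5 act per taxon across
the cohort.  Every removal is recorded with its step, reason and the
offending values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .stats_core import spearman

__all__ = [
    "RECORD_COLUMNS",
    "FilterReport",
    "load_default_blacklist",
    "read_report",
    "unique_kmer_threshold",
    "filter_low_unique_kmers",
    "filter_low_total_kmers",
    "filter_decorrelated",
    "filter_contaminant_like",
    "filter_blacklist",
    "run_decontam",
]

RECORD_COLUMNS = [
    "sample_id", "taxon_id", "name", "rank", "lineage",
    "reads", "total_kmers", "unique_kmers",
]

STEP_NAMES = {
    1: "low_unique_kmers",
    2: "low_total_kmers",
    3: "decorrelated",
    4: "contaminant_like",
    5: "blacklist",
    "insufficiency": "insufficiency",
}


@dataclass
class FilterReport:
    """Audit trail of a decontamination run.

    ``removed`` holds one row per removal decision (taxon-level for steps
    3–5, record-level reasons are aggregated per taxon for steps 1–2);
    ``retained`` lists surviving taxa.  Together they partition the input.
    """

    removed: pd.DataFrame
    retained: list
    parameters: dict = field(default_factory=dict)

    def removed_at(self, step) -> set:
        name = STEP_NAMES.get(step, step)
        return set(self.removed.loc[self.removed["step"] == name, "taxon"])

    def first_steps(self) -> pd.Series:
        """Earliest removal step per removed taxon (protocol order)."""
        order = ["low_unique_kmers", "low_total_kmers", "decorrelated",
                 "contaminant_like", "blacklist", "insufficiency"]
        df = self.removed.copy()
        df["step"] = pd.Categorical(df["step"], categories=order, ordered=True)
        return df.sort_values("step").groupby("taxon")["step"].first()


def load_default_blacklist() -> set:
    """Bundled reagent-contaminant genus list (case-insensitive names)."""
    text = (
        resources.files("hepmicro").joinpath("data/contaminant_blacklist.txt")
        .read_text()
    )
    return {
        line.strip() for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    }


# KrakenUniq-style report columns; only a subset is consumed.  A mapping
# config lets other classifier dialects supply the same fields.
DEFAULT_COLUMN_MAP = {
    "reads": "reads",
    "total_kmers": "kmers",
    "unique_kmers": "dup",  # dialect-dependent; see read_report docstring
    "taxon_id": "taxID",
    "rank": "rank",
    "name": "taxName",
}


def read_report(path, sample_id: str | None = None,
                column_map: dict | None = None) -> pd.DataFrame:
    """Read one per-sample taxonomic report (tab-separated).

    Files written by :func:`hepmicro.synthetic_data.simulate_taxon_reports`
    or by this package's own writers carry the canonical columns and need
    no mapping.  For classifier-native reports, ``column_map`` maps the
    canonical field names (reads, total_kmers, unique_kmers, taxon_id,
    rank, name) onto the file's column headers.
    """
    df = pd.read_csv(path, sep="\t")
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in ("name", "reads", "total_kmers", "unique_kmers")
               if c not in df.columns]
    if missing:
        raise ValueError(f"report {path} lacks columns: {missing}")
    if "sample_id" not in df.columns:
        df["sample_id"] = sample_id or Path(path).stem
    if "lineage" not in df.columns:
        df["lineage"] = df["name"]
    if "rank" not in df.columns:
        df["rank"] = "species"
    if "taxon_id" not in df.columns:
        df["taxon_id"] = np.arange(len(df))
    return df[RECORD_COLUMNS]


def _as_records(reports) -> pd.DataFrame:
    """Accept a dict of per-sample tables or a long table."""
    if isinstance(reports, dict):
        if not reports:
            raise ValueError("no reports supplied")
        frames = []
        for sid, df in reports.items():
            df = df.copy()
            df["sample_id"] = sid
            frames.append(df)
        records = pd.concat(frames, ignore_index=True)
    else:
        records = reports.copy()
    if records.empty:
        raise ValueError("no taxon records supplied")
    for c in ("reads", "total_kmers", "unique_kmers"):
        if (records[c] < 0).any():
            raise ValueError(f"negative values in column {c}")
    return records


def unique_kmer_threshold(read_length: int, kmer_length: int) -> int:
    """Minimum distinct k-mers a single genuine read must contribute."""
    if not (1 <= kmer_length <= read_length):
        raise ValueError("require 1 <= kmer_length <= read_length")
    return read_length - kmer_length + 1


def filter_low_unique_kmers(records: pd.DataFrame, read_length: int,
                            kmer_length: int):
    """Step 1: drop records with unique_kmers strictly below the threshold.

    Records exactly at the threshold are retained ("low" means below).
    """
    thr = unique_kmer_threshold(read_length, kmer_length)
    bad = records["unique_kmers"] < thr
    removed = records.loc[bad]
    entries = [
        {"taxon": n, "sample_id": s, "step": STEP_NAMES[1],
         "reason": f"unique_kmers {u} < threshold {thr}", "value": float(u)}
        for n, s, u in zip(removed["name"], removed["sample_id"],
                           removed["unique_kmers"])
    ]
    return records.loc[~bad].copy(), entries


def filter_low_total_kmers(records: pd.DataFrame, fold: float = 5.0):
    """Step 2: retain records whose total_kmers strictly exceed fold × reads."""
    if fold <= 0:
        raise ValueError("fold must be positive")
    ok = records["total_kmers"] > fold * records["reads"]
    removed = records.loc[~ok]
    entries = [
        {"taxon": n, "sample_id": s, "step": STEP_NAMES[2],
         "reason": f"total_kmers {t} <= {fold} x reads {r}", "value": float(t)}
        for n, s, t, r in zip(removed["name"], removed["sample_id"],
                              removed["total_kmers"], removed["reads"])
    ]
    return records.loc[ok].copy(), entries


def filter_decorrelated(records: pd.DataFrame, alpha: float = 0.05,
                        min_samples: int = 5,
                        datasets: pd.Series | None = None):
    """Step 3: drop taxa whose three statistics are not mutually correlated.

    Per taxon and per dataset, the three pairwise Spearman correlations
    among reads, total_kmers and unique_kmers are computed across the
    samples where the taxon appears.  A taxon is removed if, in any
    dataset where it is testable (>= min_samples occurrences), any
    correlation has p >= alpha or is undefined.  A taxon testable in no
    dataset is removed with reason "insufficiency".
    """
    if datasets is None:
        ds = pd.Series("all", index=records["sample_id"].unique())
    else:
        ds = datasets
    entries = []
    drop = set()
    pairs = [("reads", "total_kmers"), ("reads", "unique_kmers"),
             ("total_kmers", "unique_kmers")]
    for taxon, grp in records.groupby("name", sort=False):
        testable_anywhere = False
        for _, sub in grp.groupby(grp["sample_id"].map(ds)):
            if len(sub) < min_samples:
                continue
            testable_anywhere = True
            for a, b in pairs:
                res = spearman(sub[a].to_numpy(float), sub[b].to_numpy(float))
                if res.undefined or not (res.p_value < alpha):
                    drop.add(taxon)
                    entries.append({
                        "taxon": taxon, "sample_id": "*",
                        "step": STEP_NAMES[3],
                        "reason": (f"spearman({a},{b}) undefined"
                                   if res.undefined else
                                   f"spearman({a},{b}) p={res.p_value:.3g} >= {alpha}"),
                        "value": float("nan") if res.undefined else float(res.statistic),
                    })
                    break
            if taxon in drop:
                break
        if not testable_anywhere:
            drop.add(taxon)
            entries.append({
                "taxon": taxon, "sample_id": "*", "step": "insufficiency",
                "reason": f"present in < {min_samples} samples in every dataset",
                "value": float(len(grp)),
            })
    kept = records.loc[~records["name"].isin(drop)].copy()
    return kept, entries


def filter_contaminant_like(records: pd.DataFrame,
                            contaminant_reference: pd.DataFrame | None = None,
                            similarity_threshold: float = 0.9,
                            depth_test: bool = True,
                            alpha: float = 0.05,
                            min_samples: int = 5,
                            depth: pd.Series | None = None):
    """Step 4: drop taxa with the frequency signature of reagent contamination.

    Reagent contaminants enter at roughly constant mass per library, so
    their *relative* abundance falls as sequencing depth rises.  A taxon
    is removed when its relative abundance is significantly negatively
    Spearman-correlated with total sample read depth (rho < 0,
    p < alpha).  If a reference contaminant abundance-vs-depth profile is
    supplied, taxa whose abundance profile correlates with the reference
    above ``similarity_threshold`` are removed as well.  With the depth
    test disabled and no reference, the step is a pass-through.
    ``depth`` is the total read count per sample, ideally measured on the
    unfiltered report so the decision does not shift as other filters
    remove records (this keeps the protocol idempotent); when omitted it
    is computed from ``records``.
    """
    entries = []
    drop = set()
    if depth is None:
        depth = records.groupby("sample_id")["reads"].sum()
    if depth_test:
        for taxon, grp in records.groupby("name", sort=False):
            if len(grp) < min_samples:
                continue
            rel = grp["reads"].to_numpy(float) / depth.loc[grp["sample_id"]].to_numpy(float)
            res = spearman(rel, depth.loc[grp["sample_id"]].to_numpy(float))
            if (not res.undefined) and res.statistic < 0 and res.p_value < alpha:
                drop.add(taxon)
                entries.append({
                    "taxon": taxon, "sample_id": "*", "step": STEP_NAMES[4],
                    "reason": (f"relative abundance vs depth rho="
                               f"{res.statistic:.2f}, p={res.p_value:.3g}"),
                    "value": float(res.statistic),
                })
    if contaminant_reference is not None and len(contaminant_reference):
        # reference: columns sample_id, abundance — one known contaminant's profile
        ref = contaminant_reference.set_index("sample_id")["abundance"]
        for taxon, grp in records.groupby("name", sort=False):
            if taxon in drop:
                continue
            common = grp.set_index("sample_id")["reads"].index.intersection(ref.index)
            if len(common) < min_samples:
                continue
            x = grp.set_index("sample_id")["reads"].loc[common].to_numpy(float)
            y = ref.loc[common].to_numpy(float)
            res = spearman(x, y)
            if (not res.undefined) and res.statistic >= similarity_threshold:
                drop.add(taxon)
                entries.append({
                    "taxon": taxon, "sample_id": "*", "step": STEP_NAMES[4],
                    "reason": f"matches reference profile rho={res.statistic:.2f}",
                    "value": float(res.statistic),
                })
    kept = records.loc[~records["name"].isin(drop)].copy()
    return kept, entries


def filter_blacklist(records: pd.DataFrame, blacklist):
    """Step 5: drop taxa whose name or any lineage ancestor is blacklisted.

    Matching is case-insensitive exact-name; a blacklisted genus removes
    its species records through the lineage.
    """
    black = {str(b).lower() for b in blacklist}
    if not black:
        return records.copy(), []

    def hit(row_name: str, lineage: str):
        parts = [row_name] + str(lineage).split(";")
        for p in parts:
            if p.strip().lower() in black:
                return p.strip()
        return None

    per_taxon = records.drop_duplicates("name")[["name", "lineage"]]
    drop, entries = set(), []
    for n, lin in zip(per_taxon["name"], per_taxon["lineage"]):
        h = hit(n, lin)
        if h is not None:
            drop.add(n)
            entries.append({
                "taxon": n, "sample_id": "*", "step": STEP_NAMES[5],
                "reason": f"lineage member '{h}' in blacklist", "value": 1.0,
            })
    kept = records.loc[~records["name"].isin(drop)].copy()
    return kept, entries


def run_decontam(reports, read_length: int = 150, kmer_length: int = 31,
                 fold: float = 5.0, alpha: float = 0.05, min_samples: int = 5,
                 blacklist=None, datasets: pd.Series | None = None,
                 depth_test: bool = True,
                 contaminant_reference: pd.DataFrame | None = None,
                 sample_depth: pd.Series | None = None):
    """Run the full five-step protocol and assemble the cleaned profile.

    Parameters mirror the per-step functions.  ``blacklist`` defaults to
    the bundled reagent-contaminant genus list; ``datasets`` maps
    sample_id -> dataset label for the per-dataset correlation screen.

    Returns
    -------
    counts : DataFrame
        sample × taxon read-count matrix of retained records (species
        level; higher ranks are materialized downstream from lineages).
    report : FilterReport
    """
    records = _as_records(reports)
    input_taxa = set(records["name"])
    if sample_depth is None:
        sample_depth = records.groupby("sample_id")["reads"].sum()
    params = {
        "read_length": read_length, "kmer_length": kmer_length,
        "fold": fold, "alpha": alpha, "min_samples": min_samples,
        "depth_test": depth_test,
    }
    if blacklist is None:
        blacklist = load_default_blacklist()

    all_entries = []
    records, e1 = filter_low_unique_kmers(records, read_length, kmer_length)
    all_entries += e1
    if not records.empty:
        records, e2 = filter_low_total_kmers(records, fold)
        all_entries += e2
    if not records.empty:
        records, e3 = filter_decorrelated(records, alpha, min_samples, datasets)
        all_entries += e3
    if not records.empty:
        records, e4 = filter_contaminant_like(
            records, contaminant_reference, depth_test=depth_test,
            alpha=alpha, min_samples=min_samples, depth=sample_depth)
        all_entries += e4
    if not records.empty:
        records, e5 = filter_blacklist(records, blacklist)
        all_entries += e5

    retained = sorted(set(records["name"]))
    removed_df = pd.DataFrame(
        all_entries, columns=["taxon", "sample_id", "step", "reason", "value"]
    )
    # taxon-level partition: a taxon partially filtered at the record-level
    # steps (1-2) but still present afterwards counts as retained; its
    # record-level removals stay in the audit only if it was fully removed
    removed_df = removed_df.loc[~removed_df["taxon"].isin(retained)]
    # collapse to one row per (taxon, step): first offending record speaks
    removed_df = removed_df.drop_duplicates(subset=["taxon", "step"])
    report = FilterReport(removed=removed_df, retained=retained, parameters=params)

    if records.empty:
        counts = pd.DataFrame(dtype=float)
    else:
        counts = records.pivot_table(index="sample_id", columns="name",
                                     values="reads", aggfunc="sum",
                                     fill_value=0)
        counts.columns.name = None
    return counts, report
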