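"""Per-sample CNV load and cohort summary tables.

CNV load is summarised per individual as three variables, each split by
dosage class (all / deletions / duplications): the number of rare CNVs
carried, their total base-pair length, and the number of distinct genes
they disrupt. A gene counts as disrupted when its coordinates padded by
+/-20 kb overlap any CNV of the sample.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

CLASSES = ("all", "deletion", "duplication")
_SHORT = {"all": "all", "deletion": "del", "duplication": "dup"}


def build_gene_trees(genes: pd.DataFrame, pad_bp: int = 20_000) -> dict[str, IntervalTree]:
    """Interval trees of padded gene bodies, one per chromosome.

    Gene coordinates are 1-based inclusive; tree intervals are half-open
    [start, end+1). Padded starts are clamped at 1.
    """
    trees: dict[str, IntervalTree] = {}
    for row in genes.itertuples(index=False):
        start = max(1, int(row.start_bp) - pad_bp)
        end = int(row.end_bp) + pad_bp
        trees.setdefault(str(row.chromosome), IntervalTree()).addi(start, end + 1, row.gene_id)
    return trees


def _genes_hit(cnvs: pd.DataFrame, trees: dict[str, IntervalTree]) -> set:
    hit = set()
    for row in cnvs.itertuples(index=False):
        tree = trees.get(str(row.chromosome))
        if tree is None:
            continue
        for iv in tree.overlap(int(row.start_bp), int(row.end_bp) + 1):
            hit.add(iv.data)
    return hit


def genes_disrupted(
    cnvs_of_sample: pd.DataFrame, genes: pd.DataFrame, pad_bp: int = 20_000
) -> int:
    """Distinct genes whose padded span overlaps any CNV of one sample."""
    trees = build_gene_trees(genes, pad_bp=pad_bp)
    return len(_genes_hit(cnvs_of_sample, trees))


def compute_burden(
    rare_cnvs: pd.DataFrame,
    genes: pd.DataFrame,
    samples: pd.DataFrame,
    pad_bp: int = 20_000,
) -> pd.DataFrame:
    """Per-sample burden records, zeros for non-carriers.

    ``samples`` must have columns sample_id and cohort and covers the full
    post-QC analysis sample. Returns one row per sample with columns
    count_/length_/genes_{all,del,dup}.
    """
    known = set(samples["sample_id"])
    unknown = set(rare_cnvs["sample_id"]) - known
    if unknown:
        raise ValueError(f"CNVs for samples outside the analysis set: {sorted(unknown)[:5]}")

    trees = build_gene_trees(genes, pad_bp=pad_bp)
    records = []
    by_sample = {k: g for k, g in rare_cnvs.groupby("sample_id", sort=False)}
    for row in samples.itertuples(index=False):
        rec = {"sample_id": row.sample_id, "cohort": row.cohort}
        grp = by_sample.get(row.sample_id)
        for cls in CLASSES:
            short = _SHORT[cls]
            if grp is None:
                sub = None
            elif cls == "all":
                sub = grp
            else:
                sub = grp[grp["dosage_class"] == cls]
            if sub is None or sub.empty:
                rec[f"count_{short}"] = 0
                rec[f"length_{short}"] = 0
                rec[f"genes_{short}"] = 0
            else:
                rec[f"count_{short}"] = int(len(sub))
                rec[f"length_{short}"] = int(sub["length_bp"].sum())
                rec[f"genes_{short}"] = len(_genes_hit(sub, trees))
        records.append(rec)
    return pd.DataFrame.from_records(records)


def cohort_summary(burden_records: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Cohort summary tables of CNV load.

    Returns three tables, each with one row per cohort plus a Total row:

    - ``burden``: N, load (sum of CNV counts) and rate (load / N) for all
      CNVs, deletions and duplications;
    - ``carriers``: numbers of individuals carrying 0, 1, 2 and 3+ CNVs;
    - ``genes``: gene load (sum of per-individual distinct disrupted gene
      counts) and gene rate, by class.

    Rates are reported rounded to 3 decimals in the ``*_rate`` columns;
    exact values are in ``*_rate_exact``.
    """
    if burden_records.empty:
        raise ValueError("no burden records")
    df = burden_records
    cohorts = list(pd.unique(df["cohort"]))

    def one_block(sub: pd.DataFrame, label: str) -> tuple[dict, dict, dict]:
        n = len(sub)
        b = {"cohort": label, "n": n}
        g = {"cohort": label, "n": n}
        for cls in CLASSES:
            short = _SHORT[cls]
            load = int(sub[f"count_{short}"].sum())
            b[f"load_{short}"] = load
            b[f"rate_{short}"] = round(load / n, 3)
            b[f"rate_{short}_exact"] = load / n
            gload = int(sub[f"genes_{short}"].sum())
            g[f"gene_load_{short}"] = gload
            g[f"gene_rate_{short}"] = round(gload / n, 3)
            g[f"gene_rate_{short}_exact"] = gload / n
        counts = sub["count_all"]
        c = {
            "cohort": label,
            "carriers_0": int((counts == 0).sum()),
            "carriers_1": int((counts == 1).sum()),
            "carriers_2": int((counts == 2).sum()),
            "carriers_3plus": int((counts >= 3).sum()),
            "total": n,
        }
        return b, c, g

    burden_rows, carrier_rows, gene_rows = [], [], []
    for cohort in cohorts:
        b, c, g = one_block(df[df["cohort"] == cohort], cohort)
        burden_rows.append(b)
        carrier_rows.append(c)
        gene_rows.append(g)
    b, c, g = one_block(df, "Total")
    burden_rows.append(b)
    carrier_rows.append(c)
    gene_rows.append(g)

    return {
        "burden": pd.DataFrame(burden_rows),
        "carriers": pd.DataFrame(carrier_rows),
        "genes": pd.DataFrame(gene_rows),
    }
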