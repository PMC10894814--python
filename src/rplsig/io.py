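"""Readers and writers for the plain-text formats the pipeline touches.

TSV for expression matrices, sample annotations, survival tables and score
outputs; GMT for gene sets; matrix-market triplets for single-cell counts;
JSON for configuration, ground truth and provenance records.

Readers reject malformed input rather than coercing it; every writer
produces files its paired reader accepts.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import REGION_CODES, ExpressionMatrix, GeneSet

log = logging.getLogger("rplsig")


# ---------------------------------------------------------------- expression

def read_expression(path, scale: str = "linear") -> ExpressionMatrix:
    """Read a gene-by-sample TSV (first column gene ids, header sample ids).

    Duplicate gene ids are collapsed by summation on the linear scale and
    logged; a duplicate sample id or a non-numeric cell is a hard error
    naming the offending coordinate.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    seen_dups = sorted({h for h in header if header.count(h) > 1})
    if seen_dups:
        raise ValueError(f"{path}: duplicate sample ids {seen_dups}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at gene "
            f"{df.index[r]!r}, sample {df.columns[c]!r}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(f"{path}: missing value at gene {df.index[r]!r}, sample {df.columns[c]!r}")
    if numeric.index.has_duplicates:
        ndup = int(numeric.index.duplicated().sum())
        log.warning("%s: collapsing %d duplicate gene rows by linear-scale summation", path, ndup)
        if scale == "log2p1":
            numeric = np.log2((np.exp2(numeric) - 1.0).groupby(level=0, sort=False).sum() + 1.0)
        else:
            numeric = numeric.groupby(level=0, sort=False).sum()
    numeric.index = numeric.index.astype(str)
    numeric.index.name = None
    numeric.columns = numeric.columns.astype(str)
    return ExpressionMatrix(numeric.astype(float), scale=scale)


def write_expression(expr: ExpressionMatrix, path) -> None:
    out = expr.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.10g")


# ---------------------------------------------------------------- annotations

def read_annotations(path) -> pd.DataFrame:
    """Read a sample annotation TSV (sample_id plus optional group/region/patient_id)."""
    ann = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in ann.columns:
        raise ValueError(f"{path}: annotation table needs a sample_id column")
    if ann["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample_id in annotations")
    if "region" in ann.columns:
        bad = set(ann["region"].dropna()) - set(REGION_CODES)
        if bad:
            raise ValueError(f"{path}: unknown region codes {sorted(bad)}; expected {REGION_CODES}")
    return ann


def write_annotations(ann: pd.DataFrame, path) -> None:
    ann.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- gene sets

def read_gmt(path) -> list[GeneSet]:
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has {len(fields)} fields; need >=3")
            name, desc, *members = fields
            members = [m for m in members if m]
            uniq = list(dict.fromkeys(members))
            if len(uniq) < len(members):
                log.warning("%s:%d: deduplicated %d repeated members in set %s",
                            path, lineno, len(members) - len(uniq), name)
            sets.append(GeneSet(name, desc, uniq))
    return sets


def write_gmt(sets, path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")


# ---------------------------------------------------------------- survival

def read_survival(path) -> pd.DataFrame:
    """Read a survival TSV: sample_id, time, event, plus optional covariates.

    Enforces time > 0 and event in {0, 1}; covariate columns are typed
    numeric where fully parseable, otherwise categorical over their observed
    levels.
    """
    tab = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "time", "event"):
        if col not in tab.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    tab["time"] = pd.to_numeric(tab["time"], errors="raise")
    if (tab["time"] <= 0).any():
        bad = tab.loc[tab["time"] <= 0, "sample_id"].tolist()
        raise ValueError(f"{path}: non-positive follow-up time for samples {bad}")
    ev = pd.to_numeric(tab["event"], errors="raise")
    if not ev.isin([0, 1]).all():
        raise ValueError(f"{path}: event indicator must be 0 or 1")
    tab["event"] = ev.astype(int)
    for col in tab.columns:
        if col in ("sample_id", "time", "event"):
            continue
        numeric = pd.to_numeric(tab[col], errors="coerce")
        if numeric.notna().all():
            tab[col] = numeric
        else:
            tab[col] = tab[col].astype("category")
    tab["sample_id"] = tab["sample_id"].astype(str)
    return tab


def write_survival(tab: pd.DataFrame, path) -> None:
    tab.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- single cell

def write_single_cell(counts, genes, cells, annotations: pd.DataFrame, outdir) -> None:
    """Write counts as matrix-market triplet plus gene/cell annotation TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sparse = scipy.sparse.coo_matrix(np.asarray(counts))
    scipy.io.mmwrite(str(outdir / "counts.mtx"), sparse)
    pd.Series(list(genes), name="gene_id").to_csv(outdir / "genes.tsv", sep="\t", index=False)
    annotations.to_csv(outdir / "cells.tsv", sep="\t", index=False)


def read_single_cell(outdir):
    outdir = Path(outdir)
    counts = scipy.io.mmread(str(outdir / "counts.mtx")).toarray()
    genes = pd.read_csv(outdir / "genes.tsv", sep="\t")["gene_id"].astype(str).tolist()
    cells = pd.read_csv(outdir / "cells.tsv", sep="\t", dtype=str)
    return counts, genes, cells


# ---------------------------------------------------------------- json / provenance

def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def write_provenance(path, *, inputs: dict, params: dict, seed: int | None) -> None:
    """Record what a run saw: inputs, parameters, seed and library versions."""
    import rplsig

    record = {
        "inputs": inputs,
        "params": params,
        "seed": seed,
        "versions": {
            "rplsig": rplsig.__version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    write_json(record, path)
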