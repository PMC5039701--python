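"""Reading and writing expression matrices, manifests, fits and networks.

Expression matrices are TSV/CSV with a header row of gene identifiers and one
row per sample.  A JSON manifest declares the 2K files, one per
(platform, group) pair::

    {"entries": [{"platform": "G450", "group": "sensitive",
                  "path": "g450_sensitive.tsv"}, ...]}

Paths are resolved relative to the manifest file.  Gene sets are intersected
across files and columns reordered to the first file's order.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .diffnet import DifferentialNetwork
from .estimator import TDJGLFit
from .model_core import MultiPlatformData

__all__ = [
    "Manifest",
    "read_expression_matrix",
    "write_expression_matrix",
    "load_manifest",
    "write_manifest",
    "write_fit",
    "write_networks",
    "read_matrix_tsv",
    "write_matrix_tsv",
]


@dataclass
class Manifest:
    entries: list  # dicts with platform, group, path (and optional n)
    provenance: dict | None = None

    def __post_init__(self):
        groups = []  # first-appearance order: the first group listed is group 1
        platforms = []
        seen = set()
        for e in self.entries:
            key = (e["platform"], e["group"])
            if key in seen:
                raise ValueError(f"duplicate manifest entry for {key}")
            seen.add(key)
            if e["group"] not in groups:
                groups.append(e["group"])
            if e["platform"] not in platforms:
                platforms.append(e["platform"])
        if len(groups) != 2:
            raise ValueError(
                f"manifest must name exactly 2 groups, got {groups}"
            )
        for pf in platforms:
            for g in groups:
                if (pf, g) not in seen:
                    raise ValueError(
                        f"manifest is missing the ({pf}, {g}) data set"
                    )
        self.groups = groups
        self.platforms = platforms


def _sep_for(path: Path, fmt: str | None) -> str:
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "tsv"
    if fmt not in {"tsv", "csv"}:
        raise ValueError("fmt must be 'tsv' or 'csv'")
    return "," if fmt == "csv" else "\t"


def read_expression_matrix(
    path, fmt: str | None = None, log_transform: bool = False
):
    """Read a samples-by-genes matrix; returns (array, gene names).

    Rejects non-numeric or missing cells (reported with row/column) and
    duplicated gene names.  ``log_transform`` applies log2(x + 1)."""
    path = Path(path)
    sep = _sep_for(path, fmt)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").rstrip("\r")
    genes = header.split(sep)
    if len(set(genes)) != len(genes):
        dup = sorted({g for g in genes if genes.count(g) > 1})
        raise ValueError(f"duplicated gene name(s) in {path.name}: {dup}")
    df = pd.read_csv(path, sep=sep, header=0, names=genes)
    body = df.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(body.isna().to_numpy())
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"non-numeric or missing value in {path.name} at sample row "
            f"{r + 1}, gene '{genes[c]}'"
        )
    X = body.to_numpy(dtype=float)
    if log_transform:
        if X.min() < 0:
            raise ValueError("log transform requires nonnegative values")
        X = np.log2(X + 1.0)
    return X, genes


def write_expression_matrix(X, genes, path, fmt: str | None = None) -> None:
    path = Path(path)
    pd.DataFrame(np.asarray(X), columns=list(genes)).to_csv(
        path, sep=_sep_for(path, fmt), index=False, float_format="%.10g"
    )


def load_manifest(
    path, log_transform: bool = False
) -> tuple[MultiPlatformData, Manifest]:
    """Load all 2K matrices declared in a JSON manifest.

    Gene sets are intersected (error when fewer than 2 genes remain) and
    columns reordered to the first file's gene order."""
    path = Path(path)
    raw = json.loads(path.read_text())
    manifest = Manifest(
        entries=raw["entries"], provenance=raw.get("provenance")
    )
    loaded = {}
    for e in manifest.entries:
        fpath = (path.parent / e["path"]).resolve()
        X, genes = read_expression_matrix(fpath, log_transform=log_transform)
        if "n" in e and e["n"] != X.shape[0]:
            raise ValueError(
                f"{fpath.name}: manifest declares n={e['n']} but file has "
                f"{X.shape[0]} rows"
            )
        loaded[(e["platform"], e["group"])] = (X, genes)
    first_genes = loaded[(manifest.platforms[0], manifest.groups[0])][1]
    common = set(first_genes)
    for X, genes in loaded.values():
        common &= set(genes)
    if len(common) < 2:
        raise ValueError(
            f"gene intersection across files has {len(common)} genes; need >= 2"
        )
    order = [g for g in first_genes if g in common]
    X_nested = []
    for pf in manifest.platforms:
        row = []
        for g in manifest.groups:
            X, genes = loaded[(pf, g)]
            idx = [genes.index(name) for name in order]
            row.append(X[:, idx])
        X_nested.append(row)
    data = MultiPlatformData(
        X=X_nested,
        genes=order,
        group_labels=tuple(manifest.groups),
        platform_labels=list(manifest.platforms),
    )
    return data, manifest


def write_manifest(entries, path, provenance: dict | None = None) -> None:
    payload = {"entries": entries}
    if provenance:
        payload["provenance"] = provenance
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def write_matrix_tsv(M, genes, path) -> None:
    """Dense square matrix with gene-name header and row labels."""
    pd.DataFrame(np.asarray(M), index=list(genes), columns=list(genes)).to_csv(
        path, sep="\t", float_format="%.10g"
    )


def read_matrix_tsv(path):
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), list(df.columns)


def config_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def write_fit(
    fit: TDJGLFit,
    genes,
    out_dir,
    platform_labels=None,
    group_labels=("group1", "group2"),
    seed: int | None = None,
) -> None:
    """Precision TSVs per (platform, group) plus a JSON fit report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prec = fit.precisions
    if platform_labels is None:
        platform_labels = [f"platform{k + 1}" for k in range(prec.K)]
    for k in range(prec.K):
        for c in range(2):
            stem = f"{platform_labels[k]}_{group_labels[c]}"
            write_matrix_tsv(prec.Theta[k][c], genes, out / f"theta_{stem}.tsv")
            if prec.Z is not None:
                write_matrix_tsv(prec.Z[k][c], genes, out / f"z_{stem}.tsv")
    report = {
        "method": fit.method,
        "lambda1": fit.lambda1,
        "lambda2": fit.lambda2,
        "objective_trace": [float(v) for v in fit.objective_trace],
        "outer_iterations": fit.outer_iterations,
        "converged": bool(fit.converged),
        "seed": seed,
        "config_hash": config_hash(
            {"lambda1": fit.lambda1, "lambda2": fit.lambda2, "seed": seed}
        ),
    }
    (out / "fit_report.json").write_text(json.dumps(report, indent=2) + "\n")


def read_fit_report(out_dir) -> dict:
    return json.loads((Path(out_dir) / "fit_report.json").read_text())


def write_networks(net: DifferentialNetwork, out_dir) -> None:
    """Edge-list TSVs: one per platform plus the cross-platform consensus."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for k in range(net.K):
        rows = [
            {
                "gene_i": net.genes[i],
                "gene_j": net.genes[j],
                "platform": net.platform_labels[k],
                "score": net.scores[k][i, j],
                "sign": sign,
                "strength": strength,
            }
            for (i, j), (strength, sign) in sorted(net.diff_edges[k].items())
        ]
        pd.DataFrame(
            rows,
            columns=["gene_i", "gene_j", "platform", "score", "sign", "strength"],
        ).to_csv(
            out / f"diff_edges_{net.platform_labels[k]}.tsv",
            sep="\t",
            index=False,
            float_format="%.10g",
        )
    rows = []
    for i, j in sorted(net.consensus_edges):
        row = {"gene_i": net.genes[i], "gene_j": net.genes[j]}
        for k in range(net.K):
            row[f"score_{net.platform_labels[k]}"] = net.scores[k][i, j]
        rows.append(row)
    pd.DataFrame(rows).to_csv(
        out / "consensus_edges.tsv", sep="\t", index=False, float_format="%.10g"
    )
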