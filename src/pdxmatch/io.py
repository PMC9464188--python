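"""Reading and writing the pipeline's standard file formats.

Expression matrices, proportions, and profiles travel as TSV/CSV with
genes (or samples) in rows and a named identifier column; gene sets come
from standard GMT; configuration from YAML; results and manifests as
JSON. Matrix orientation is fixed as genes-in-rows for expression (the
Xena dialect); a table that looks transposed is rejected with guidance
rather than silently auto-transposed.
"""
from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from pandas.errors import ParserError

from .containers import (
    LINEAR,
    LOG2P1,
    OTHER,
    SIMPLEX,
    SUB_SIMPLEX,
    CellTypeProfiles,
    ExpressionMatrix,
    ProportionMatrix,
)
from .immune import SignatureMatrix


def _sep_for(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def _read_table(path, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(
            path, sep=_sep_for(path), index_col=0,
            float_precision="round_trip", **kw,
        )
    except ParserError as exc:  # pandas reports the offending line number
        raise ValueError(f"parse error in {path}: {exc}") from exc


def read_expression_matrix(
    path, scale: str = LINEAR, na_action: str = "error"
) -> ExpressionMatrix:
    """Load a genes x samples TSV/CSV as a linear-scale ExpressionMatrix.

    ``scale="log2p1"`` inputs are converted to linear (2**x - 1) on load.
    Duplicate gene rows are summed with a warning. Missing values raise
    by default; ``na_action="zero"`` imputes them as zero instead.
    """
    df = _read_table(path)
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    df = df.apply(pd.to_numeric, errors="raise")

    if df.isna().to_numpy().any():
        if na_action == "zero":
            df = df.fillna(0.0)
        else:
            raise ValueError(f"missing values in {path} (use na_action='zero' to impute)")

    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        warnings.warn(f"summing duplicate gene rows: {dups[:5]}", stacklevel=2)
        df = df.groupby(level=0, sort=False).sum()

    n_genes, n_samples = df.shape
    if n_samples > 20 * max(n_genes, 1) and n_genes < 500:
        raise ValueError(
            f"{path} has {n_genes} rows and {n_samples} columns; expression "
            "tables must have genes in rows — the input looks transposed"
        )

    em = ExpressionMatrix(df, scale=scale)  # validates non-negativity
    return em.to_linear()


def write_expression_matrix(em: ExpressionMatrix, path) -> None:
    em.data.to_csv(path, sep=_sep_for(path), index_label="gene_id")


def read_proportions(path) -> ProportionMatrix:
    df = _read_table(path)
    df.index.name = "sample_id"
    constraint = SUB_SIMPLEX if OTHER in df.columns else SIMPLEX
    return ProportionMatrix(df, row_constraint=constraint)


def write_proportions(props: ProportionMatrix, path) -> None:
    props.data.to_csv(path, sep=_sep_for(path), index_label="sample_id")


def write_profiles(profiles: CellTypeProfiles, prefix) -> list[Path]:
    """Write profile values (+stderr if present) and a metadata sidecar.

    Produces ``<prefix>.values.tsv``, optionally ``<prefix>.stderr.tsv``,
    and ``<prefix>.meta.json`` (sample count for downstream degrees of
    freedom). Returns the written paths.
    """
    prefix = Path(prefix)
    written = []
    p = prefix.with_suffix(".values.tsv")
    profiles.values.to_csv(p, sep="\t", index_label="gene_id")
    written.append(p)
    if profiles.stderr is not None:
        p = prefix.with_suffix(".stderr.tsv")
        profiles.stderr.to_csv(p, sep="\t", index_label="gene_id")
        written.append(p)
    meta = {"n_samples": profiles.n_samples, "cell_types": profiles.cell_types}
    p = prefix.with_suffix(".meta.json")
    p.write_text(json.dumps(meta, indent=1))
    written.append(p)
    return written


def read_profiles(prefix) -> CellTypeProfiles:
    prefix = Path(prefix)
    values = _read_table(prefix.with_suffix(".values.tsv"))
    stderr_path = prefix.with_suffix(".stderr.tsv")
    stderr = _read_table(stderr_path) if stderr_path.exists() else None
    meta_path = prefix.with_suffix(".meta.json")
    n_samples = None
    if meta_path.exists():
        n_samples = json.loads(meta_path.read_text()).get("n_samples")
    return CellTypeProfiles(values=values, stderr=stderr, n_samples=n_samples)


def read_signature_matrix(path) -> SignatureMatrix:
    df = _read_table(path)
    df.index.name = "gene_id"
    return SignatureMatrix(df)


def write_signature_matrix(sig: SignatureMatrix, path) -> None:
    sig.data.to_csv(path, sep=_sep_for(path), index_label="gene_id")


def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT file: name, description, then tab-separated genes.

    Genes are de-duplicated preserving order; empty sets are dropped with
    a warning; a line without at least a name and description is a parse
    error naming the line.
    """
    sets: dict[str, list[str]] = {}
    text = Path(path).read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise ValueError(
                f"malformed GMT line {lineno} in {path}: expected "
                "name<TAB>description<TAB>genes..."
            )
        name, genes = fields[0], [g for g in fields[2:] if g]
        genes = list(dict.fromkeys(genes))
        if not genes:
            warnings.warn(f"dropping empty gene set {name!r} (line {lineno})", stacklevel=2)
            continue
        sets[name] = genes
    if not sets:
        warnings.warn(f"no gene sets read from {path}", stacklevel=2)
    return sets


def write_gmt(collections: dict[str, list[str]], path) -> None:
    lines = [
        "\t".join([name, name, *genes]) for name, genes in collections.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def write_match_results(matches: pd.DataFrame, path) -> None:
    matches.to_csv(path, sep="\t", index_label="sample_id")


def write_partition(partition, path) -> None:
    partition.labels.to_csv(path, sep="\t", index_label="sample_id", header=["label"])


def sha256_of_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
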