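"""Readers and writers for the pipeline's plain-text exchange formats.

Everything is TSV, GMT (one term per line: term, description, genes) or
YAML; matrices carry their axis labels, so every stage can be run from
files as well as in memory.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .containers import AnnotationCatalog, EvidenceRecord, ExpressionDataset, SyntheticConfig


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    matrix.to_csv(path, sep="\t")
    return path


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression(data: ExpressionDataset, outdir: str | Path, prefix: str = "expression") -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "values": outdir / f"{prefix}_values.tsv",
        "design": outdir / f"{prefix}_design.tsv",
        "present": outdir / f"{prefix}_present.tsv",
    }
    data.values.to_csv(paths["values"], sep="\t")
    data.design.to_csv(paths["design"], sep="\t")
    data.present.astype(int).to_csv(paths["present"], sep="\t")
    return paths


def read_expression(outdir: str | Path, prefix: str = "expression") -> ExpressionDataset:
    outdir = Path(outdir)
    values = read_matrix(outdir / f"{prefix}_values.tsv")
    design = pd.read_csv(outdir / f"{prefix}_design.tsv", sep="\t", index_col=0)
    present = read_matrix(outdir / f"{prefix}_present.tsv").astype(bool)
    return ExpressionDataset(values=values, design=design, present=present)


def write_gmt(catalog: AnnotationCatalog, path: str | Path) -> Path:
    path = Path(path)
    lines = [
        "\t".join([term, "na", *sorted(genes)]) for term, genes in sorted(catalog.terms.items())
    ]
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    return path


def read_gmt(path: str | Path) -> AnnotationCatalog:
    terms: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        terms[fields[0]] = fields[2:]
    return AnnotationCatalog(terms)


def write_evidence(records: list[EvidenceRecord], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        [
            {
                "tf": r.tf,
                "gene": r.gene,
                "source_class": r.source_class,
                "co_citations": r.co_citations,
                "provenance": r.provenance or "",
            }
            for r in records
        ],
        columns=["tf", "gene", "source_class", "co_citations", "provenance"],
    )
    df.to_csv(path, sep="\t", index=False)
    return path


def read_evidence(path: str | Path) -> list[EvidenceRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"provenance": str}, keep_default_na=False)
    return [
        EvidenceRecord(
            tf=row.tf,
            gene=row.gene,
            source_class=row.source_class,
            co_citations=int(row.co_citations),
            provenance=row.provenance or None,
        )
        for row in df.itertuples()
    ]


def write_motif_hits(hits: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    out = hits.copy()
    out["conserved"] = out["conserved"].astype(int)
    out.to_csv(path, sep="\t", index=False)
    return path


def read_motif_hits(path: str | Path) -> pd.DataFrame:
    hits = pd.read_csv(path, sep="\t")
    hits["conserved"] = hits["conserved"].astype(bool)
    return hits


def write_motif_tf_map(mapping: dict[str, list[str]], path: str | Path) -> Path:
    path = Path(path)
    rows = [{"motif": m, "tfs": ",".join(tfs)} for m, tfs in sorted(mapping.items())]
    pd.DataFrame(rows, columns=["motif", "tfs"]).to_csv(path, sep="\t", index=False)
    return path


def read_motif_tf_map(path: str | Path) -> dict[str, list[str]]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return {row.motif: [t for t in row.tfs.split(",") if t] for row in df.itertuples()}


def write_config(config: SyntheticConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    return path


def read_config(path: str | Path) -> SyntheticConfig:
    payload = yaml.safe_load(Path(path).read_text()) or {}
    return SyntheticConfig(**payload)


def write_edge_list(edges: set[tuple[str, str]], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(sorted(edges), columns=["tf", "gene"])
    df.to_csv(path, sep="\t", index=False)
    return path


def read_edge_list(path: str | Path) -> set[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t")
    return {(row.tf, row.gene) for row in df.itertuples()}
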