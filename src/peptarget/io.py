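"""Readers and writers for the pipeline's file formats.

All tables are TSV with a header row, UTF-8, "." decimal separator, empty
cells for missing values and literal ON/OFF tokens.  Graphs are SIF
("nodeA<TAB>pp<TAB>nodeB") or two-column edge TSV; sequences FASTA; spectra
two-column (m/z, intensity) TSV.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "read_table",
    "write_table",
    "read_accessions",
    "read_fasta",
    "write_fasta",
    "read_graph",
    "write_sif",
    "read_annotations",
    "read_complexes",
    "read_spectrum",
    "write_spectrum",
]


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False).replace("", np.nan)


def write_table(df: pd.DataFrame, path: str | os.PathLike, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, na_rep="")


def read_accessions(path: str | os.PathLike, column: str = "accession") -> list[str]:
    """Accessions from a TSV table (named column if present, else first column)."""
    df = read_table(path)
    col = column if column in df.columns else df.columns[0]
    return [a for a in df[col].dropna().astype(str) if a]


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Accession -> sequence; the accession is the record id up to the first '|' field rules of UniProt headers."""
    sequences = {}
    for record in SeqIO.parse(str(path), "fasta"):
        parts = record.id.split("|")
        acc = parts[1] if len(parts) >= 2 else parts[0]
        sequences[acc] = str(record.seq).upper()
    return sequences


def write_fasta(sequences: Mapping[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(seq), id=acc, description="") for acc, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_graph(path: str | os.PathLike) -> nx.Graph:
    """Undirected graph from SIF (node<TAB>relation<TAB>node...) or 2-column edge TSV."""
    g = nx.Graph()
    with open(path, encoding="utf-8") as fh:
        first = True
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2 or not fields[0]:
                continue
            if first and {f.lower() for f in fields[:2]} & {"source", "target", "nodea", "nodeb"}:
                first = False
                continue  # header row of an edge TSV
            first = False
            if len(fields) >= 3:
                u, targets = fields[0], fields[2:]
            else:
                u, targets = fields[0], fields[1:2]
            for v in targets:
                if v and v != u:
                    g.add_edge(u, v)
                elif v == u:
                    g.add_edge(u, v)  # explicit self-edge preserved
    return g


def write_sif(graph: nx.Graph, path: str | os.PathLike, relation: str = "pp") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in sorted((min(u, v), max(u, v)) for u, v in graph.edges):
            fh.write(f"{u}\t{relation}\t{v}\n")


def read_annotations(path: str | os.PathLike) -> dict[str, set[str]]:
    """term -> accession set from a (term, [name,] accession) TSV."""
    df = read_table(path)
    term_col = df.columns[0]
    acc_col = "accession" if "accession" in df.columns else df.columns[-1]
    out: dict[str, set[str]] = {}
    for term, acc in zip(df[term_col], df[acc_col]):
        if pd.isna(term) or pd.isna(acc):
            continue
        out.setdefault(str(term), set()).add(str(acc))
    return out


def read_complexes(path: str | os.PathLike) -> dict[str, set[str]]:
    """complex id -> member set; same layout as annotations."""
    return read_annotations(path)


def read_spectrum(path: str | os.PathLike) -> tuple[np.ndarray, np.ndarray]:
    arr = np.loadtxt(path, delimiter="\t", ndmin=2)
    return arr[:, 0], arr[:, 1]


def write_spectrum(grid: np.ndarray, intensity: np.ndarray, path: str | os.PathLike) -> None:
    np.savetxt(path, np.column_stack([grid, intensity]), delimiter="\t", fmt="%.6f")
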