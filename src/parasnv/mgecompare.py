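"""Pairwise identity matrices for mobile genetic element homologs.

For each named element (insertion sequences, composite transposons) present
in two or more populations, a symmetric matrix of global-alignment nucleotide
identities is computed. End-to-end alignment is deliberate: a truncated
homolog scores roughly its retained fraction, which is how partial element
copies are distinguished from full-length transfers.

The congruence check asks whether an element's identity pattern recapitulates
the clade structure of its host genomes: a vertically inherited element has
every within-clade identity above every between-clade identity; a
horizontally transferred element breaks that ordering.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .orthomap import global_identity
from .simdata import MagRecord, MgeInsertion

MGE_TABLE_COLUMNS = ["mag_id", "mge_name", "contig", "start", "end", "kind", "truncated"]


@dataclass
class MgeRecord:
    mag_id: str
    mge_name: str
    contig: str
    start: int
    end: int
    sequence: str
    kind: str = "insertion_sequence"
    truncated: bool = False

    def __post_init__(self):
        if self.end - self.start != len(self.sequence):
            raise ValueError(f"{self.mge_name}@{self.mag_id}: interval/sequence length mismatch")


def records_from_truth(
    insertions: Iterable[MgeInsertion], mags: Mapping[str, MagRecord]
) -> list[MgeRecord]:
    records = []
    for m in insertions:
        seq = mags[m.mag_id].contigs[m.contig][m.start:m.end]
        if seq != m.sequence:
            raise ValueError(f"{m.mge_name}@{m.mag_id}: truth sequence is stale")
        records.append(MgeRecord(m.mag_id, m.mge_name, m.contig, m.start, m.end,
                                 seq, truncated=m.truncated))
    return records


def records_from_table(table: pd.DataFrame, mags: Mapping[str, MagRecord]) -> list[MgeRecord]:
    """Materialize element records from an annotation table (mag_id,
    mge_name, contig, start, end[, kind]) by slicing the host contigs."""
    records = []
    for row in table.itertuples(index=False):
        seq = mags[row.mag_id].contigs[row.contig][int(row.start):int(row.end)]
        records.append(
            MgeRecord(row.mag_id, row.mge_name, row.contig, int(row.start), int(row.end),
                      seq, kind=getattr(row, "kind", "insertion_sequence"),
                      truncated=bool(getattr(row, "truncated", False)))
        )
    return records


def mge_identity_matrix(
    records: Sequence[MgeRecord], mag_order: Sequence[str] | None = None
) -> pd.DataFrame:
    """Symmetric fractional-identity matrix for one element's homologs.

    Populations lacking the element are absent (NaN); the diagonal is 1.0
    for carriers. When a population carries several copies the longest is
    used.
    """
    names = {r.mge_name for r in records}
    if len(names) != 1:
        raise ValueError(f"records span multiple element names: {sorted(names)}")
    best: dict[str, MgeRecord] = {}
    for r in records:
        if r.mag_id not in best or len(r.sequence) > len(best[r.mag_id].sequence):
            best[r.mag_id] = r
    order = list(mag_order) if mag_order is not None else sorted(best)
    mat = pd.DataFrame(np.nan, index=order, columns=order, dtype=float)
    for mag in best:
        if mag in mat.index:
            mat.loc[mag, mag] = 1.0
    for a, b in itertools.combinations(sorted(best), 2):
        if a in mat.index and b in mat.index:
            ident = global_identity(best[a].sequence, best[b].sequence)
            mat.loc[a, b] = mat.loc[b, a] = ident
    return mat


def clade_congruence(matrix: pd.DataFrame, clades: Mapping[str, str]) -> str:
    """Does the identity pattern recapitulate clade structure?

    congruent   — min within-clade identity > max between-clade identity
    incongruent — some between-clade identity exceeds some within-clade one
    undetermined — exact tie, or fewer than two carriers in either clade
    """
    present = [m for m in matrix.index if not np.isnan(matrix.loc[m, m])]
    by_clade: dict[str, list[str]] = {}
    for m in present:
        by_clade.setdefault(clades[m], []).append(m)
    if len(by_clade) < 2 or any(len(v) < 2 for v in by_clade.values()):
        return "undetermined"
    within, between = [], []
    for a, b in itertools.combinations(present, 2):
        v = matrix.loc[a, b]
        if np.isnan(v):
            continue
        (within if clades[a] == clades[b] else between).append(float(v))
    if not within or not between:
        return "undetermined"
    if min(within) > max(between):
        return "congruent"
    if max(between) > min(within):
        return "incongruent"
    return "undetermined"


def write_identity_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", na_rep="NA")


def read_mge_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"mag_id": str, "mge_name": str, "contig": str})
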