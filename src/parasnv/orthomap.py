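"""Protein clustering across populations and homologous-site mapping.

"Same site" across two genomes is only meaningful once their ORFs have been
grouped into clusters of homologous proteins and the nucleotide coordinates
of the member ORFs put in correspondence. Clustering uses the canonical
greedy incremental strategy (longest sequence founds the first cluster; each
subsequent sequence joins the first cluster whose representative it matches
at >= the identity threshold, else founds its own).

Identity is computed from an optimal unit-cost global alignment:
matched columns / total alignment columns (gaps count in the denominator).
Site maps record, for every member ORF, which representative-ORF coordinate
each member coordinate aligns to; member-member correspondence is composed
through the representative, which makes the correspondence transitively
consistent by construction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def _align(a: str, b: str) -> dict:
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    return edlib.align(a, b, mode="NW", task="path")


def global_identity(a: str, b: str) -> float:
    """Matched columns / alignment columns under optimal global alignment."""
    res = _align(a, b)
    columns = sum(int(n) for n, _ in _CIGAR_RE.findall(res["cigar"]))
    return (columns - res["editDistance"]) / columns


def alignment_column_pairs(a: str, b: str) -> np.ndarray:
    """(i, j) coordinate pairs for every aligned (non-gap/non-gap) column.

    Substitution columns are included: two sequences can disagree at a site
    and still share the site.
    """
    res = _align(a, b)
    pairs = []
    i = j = 0
    for n, op in _CIGAR_RE.findall(res["cigar"]):
        n = int(n)
        if op in "=XM":
            pairs.append(np.stack([np.arange(i, i + n), np.arange(j, j + n)], axis=1))
            i += n
            j += n
        elif op == "I":  # consumes query (a)
            i += n
        else:  # D consumes target (b)
            j += n
    if not pairs:
        return np.empty((0, 2), dtype=np.int64)
    return np.concatenate(pairs)


@dataclass
class ProteinCluster:
    cluster_id: str
    representative: tuple[str, str]  # (mag_id, orf_id)
    members: list[tuple[str, str, float]] = field(default_factory=list)

    @property
    def member_keys(self) -> list[tuple[str, str]]:
        return [(m, o) for m, o, _ in self.members]


def cluster_proteins(
    proteins: Mapping[tuple[str, str], str],
    identity_threshold: float = 0.90,
) -> list[ProteinCluster]:
    """Greedy incremental clustering of proteins across all populations.

    Sequences are processed longest-first (ties broken lexicographically by
    (mag_id, orf_id)), so the clustering is invariant to input order. A
    cheap length-ratio screen (identity can never exceed min/max length)
    avoids most alignments.
    """
    if not proteins:
        raise ValueError("no proteins to cluster")
    for key, seq in proteins.items():
        if not seq:
            raise ValueError(f"empty protein sequence for {key}")
    order = sorted(proteins, key=lambda k: (-len(proteins[k]), k))
    clusters: list[ProteinCluster] = []
    rep_seqs: list[str] = []
    for key in order:
        seq = proteins[key]
        placed = False
        for cluster, rep in zip(clusters, rep_seqs):
            la, lb = len(seq), len(rep)
            if min(la, lb) / max(la, lb) < identity_threshold:
                continue
            ident = global_identity(seq, rep)
            if ident >= identity_threshold:
                cluster.members.append((key[0], key[1], ident))
                placed = True
                break
        if not placed:
            cid = f"PC{len(clusters) + 1:05d}"
            clusters.append(ProteinCluster(cid, key, [(key[0], key[1], 1.0)]))
            rep_seqs.append(seq)
    return clusters


@dataclass
class SiteMap:
    """Coordinate correspondence of a cluster's ORFs, via the representative.

    ``to_rep[(mag, orf)]`` maps member nucleotide coordinates (coding strand)
    to representative coordinates; -1 marks unaligned (gap) positions.
    """

    cluster_id: str
    representative: tuple[str, str]
    rep_length: int
    to_rep: dict[tuple[str, str], np.ndarray]

    def rep_position(self, member: tuple[str, str], position: int) -> int | None:
        arr = self.to_rep[member]
        if not (0 <= position < len(arr)):
            raise IndexError(f"position {position} outside ORF {member}")
        v = int(arr[position])
        return None if v < 0 else v

    def map_position(
        self, src: tuple[str, str], position: int, dst: tuple[str, str]
    ) -> int | None:
        """Map a coding-strand coordinate from one member ORF to another."""
        rp = self.rep_position(src, position)
        if rp is None:
            return None
        arr = self.to_rep[dst]
        hits = np.nonzero(arr == rp)[0]
        return int(hits[0]) if hits.size else None


def map_sites(
    cluster: ProteinCluster, orf_nt_seqs: Mapping[tuple[str, str], str]
) -> SiteMap:
    """Align every member ORF (nucleotide, coding strand) to the cluster
    representative and record the aligned-column correspondence."""
    rep_key = cluster.representative
    if rep_key not in orf_nt_seqs:
        raise KeyError(f"missing nucleotide sequence for representative {rep_key}")
    rep_seq = orf_nt_seqs[rep_key]
    to_rep: dict[tuple[str, str], np.ndarray] = {}
    for mag_id, orf_id, _ in cluster.members:
        key = (mag_id, orf_id)
        if key not in orf_nt_seqs:
            raise KeyError(f"missing nucleotide sequence for cluster member {key}")
        seq = orf_nt_seqs[key]
        arr = np.full(len(seq), -1, dtype=np.int64)
        pairs = alignment_column_pairs(seq, rep_seq)
        if pairs.size:
            arr[pairs[:, 0]] = pairs[:, 1]
        to_rep[key] = arr
    return SiteMap(cluster.cluster_id, rep_key, len(rep_seq), to_rep)


def build_site_maps(
    clusters: Sequence[ProteinCluster],
    orf_nt_seqs: Mapping[tuple[str, str], str],
    skip_singletons: bool = True,
) -> dict[str, SiteMap]:
    """Site maps for every (multi-member) cluster."""
    maps = {}
    for cluster in clusters:
        if skip_singletons and len(cluster.members) < 2:
            continue
        maps[cluster.cluster_id] = map_sites(cluster, orf_nt_seqs)
    return maps


def cluster_table(clusters: Sequence[ProteinCluster]) -> pd.DataFrame:
    rows = [
        {"cluster_id": c.cluster_id, "mag_id": m, "orf_id": o,
         "identity_to_representative": ident,
         "is_representative": (m, o) == c.representative}
        for c in clusters
        for m, o, ident in c.members
    ]
    return pd.DataFrame(rows, columns=["cluster_id", "mag_id", "orf_id",
                                       "identity_to_representative",
                                       "is_representative"])


def orf_to_cluster(clusters: Sequence[ProteinCluster]) -> dict[tuple[str, str], str]:
    mapping: dict[tuple[str, str], str] = {}
    for c in clusters:
        for m, o, _ in c.members:
            key = (m, o)
            if key in mapping:
                raise ValueError(f"{key} assigned to two clusters")
            mapping[key] = c.cluster_id
    return mapping


def write_cluster_table(clusters: Sequence[ProteinCluster], path: str | Path) -> None:
    cluster_table(clusters).to_csv(path, sep="\t", index=False)
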