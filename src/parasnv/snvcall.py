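"""Curated SNV calling from mapped read-pair observations.

Each population genome serves as its own reference. The filter chain follows
the strain-level microdiversity workflow used for metagenome-assembled
genomes:

1. read pairs with identity to the reference < 90% are discarded;
2. both mates must carry mapping quality >= 1;
3. insert sizes must lie in [50 bp, 3x the median insert] (median computed
   over pairs surviving the identity and mapQ filters; bounds inclusive);
4. the consensus base at each site must also carry the highest mean mapQ;
5. a variant needs >= 2 supporting reads and frequency >= 0.05 (the source
   caller's default frequency floor);
6. sites where the variant reaches >= 40% of mapped reads are "consensus
   SNVs" — ambiguous allelic heterogeneity — and are discarded.

Only SNVs inside ORFs enter the downstream shared-SNV analysis; totals for
both the genome-wide and in-ORF sets are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence
import warnings

import numpy as np
import pandas as pd

from .simdata import BASES, MagRecord, Orf, encode

SNV_TABLE_COLUMNS = [
    "mag_id", "contig", "position", "orf_id", "position_in_orf",
    "consensus_base", "variant_base", "variant_frequency", "depth",
    "orf_nt_sequence", "protein_sequence", "cluster_id", "annotation",
]


@dataclass
class FilterLog:
    """Per-filter removal counts; input = retained + sum(removed)."""

    n_input: int = 0
    removed_identity: int = 0
    removed_mapq: int = 0
    removed_insert_short: int = 0
    removed_insert_long: int = 0
    n_retained: int = 0
    median_insert: float = float("nan")

    @property
    def total_removed(self) -> int:
        return (self.removed_identity + self.removed_mapq
                + self.removed_insert_short + self.removed_insert_long)


@dataclass
class CallLog:
    n_candidate_sites: int = 0
    n_consensus_snv_discarded: int = 0
    n_tie_rejected: int = 0
    n_mapq_rejected: int = 0
    n_below_frequency_floor: int = 0
    n_emitted: int = 0


@dataclass
class PileupSite:
    """Base counts and summed mapQ at one reference position."""

    contig: str
    position: int
    base_counts: np.ndarray  # shape (4,), A/C/G/T
    mapq_sums: np.ndarray  # shape (4,)

    @property
    def depth(self) -> int:
        return int(self.base_counts.sum())

    def mean_mapq(self, base_index: int) -> float:
        c = self.base_counts[base_index]
        return float(self.mapq_sums[base_index] / c) if c else float("nan")


@dataclass
class SnvRecord:
    mag_id: str
    contig: str
    position: int
    consensus_base: str
    variant_base: str
    variant_frequency: float
    depth: int
    orf_id: str | None = None
    position_in_orf: int | None = None
    orf_nt_sequence: str | None = None
    protein_sequence: str | None = None
    cluster_id: str | None = None
    annotation: str | None = None

    def __post_init__(self):
        if self.variant_base == self.consensus_base:
            raise ValueError("variant base equals consensus base")
        if not (0 < self.variant_frequency < 1):
            raise ValueError("variant frequency outside (0, 1)")


def filter_read_pairs(
    pairs: pd.DataFrame,
    min_pair_identity: float = 0.90,
    min_mapq: int = 1,
    min_insert: int = 50,
    max_insert_factor: float = 3.0,
) -> tuple[pd.DataFrame, FilterLog]:
    """Apply the identity / mapQ / insert-size filter chain (two-pass).

    The insert-size window is anchored on the median insert of the pairs that
    already passed the identity and mapQ filters; both bounds are inclusive,
    so a pair at exactly 3x the median is retained and identity exactly at
    the threshold is retained (only pairs strictly below 90% are discarded).
    """
    log = FilterLog(n_input=len(pairs))
    ok_id = pairs["pair_identity"] >= min_pair_identity
    log.removed_identity = int((~ok_id).sum())
    ok_mapq = (pairs["mapq1"] >= min_mapq) & (pairs["mapq2"] >= min_mapq)
    log.removed_mapq = int((ok_id & ~ok_mapq).sum())
    stage1 = pairs[ok_id & ok_mapq]
    if len(stage1) == 0:
        warnings.warn("no read pairs survive the identity/mapQ filters")
        return stage1.copy(), log
    median = float(stage1["insert_size"].median())
    log.median_insert = median
    short = stage1["insert_size"] < min_insert
    long = ~short & (stage1["insert_size"] > max_insert_factor * median)
    log.removed_insert_short = int(short.sum())
    log.removed_insert_long = int(long.sum())
    retained = stage1[~short & ~long].copy()
    log.n_retained = len(retained)
    return retained, log


class ContigPileup:
    """Dense per-position base counts for one contig."""

    def __init__(self, contig: str, length: int):
        self.contig = contig
        self.counts = np.zeros((length, 4), dtype=np.int64)
        self.mapq_sums = np.zeros((length, 4), dtype=np.int64)

    def site(self, position: int) -> PileupSite:
        return PileupSite(self.contig, position,
                          self.counts[position], self.mapq_sums[position])

    def covered_positions(self) -> np.ndarray:
        return np.nonzero(self.counts.sum(axis=1))[0]


def build_pileup(pairs: pd.DataFrame, mag: MagRecord) -> dict[str, ContigPileup]:
    """Accumulate base counts and mapQ sums per reference position.

    Both mates of a pair are counted, including where they overlap (each
    retained read base is counted exactly once).
    """
    pileups = {name: ContigPileup(name, len(seq)) for name, seq in mag.contigs.items()}
    for contig, group in pairs.groupby("contig", sort=False):
        if contig not in pileups:
            raise ValueError(f"read pairs reference unknown contig {contig!r}")
        pile = pileups[contig]
        length = pile.counts.shape[0]
        for start_col, base_col, mapq_col in (
            ("mate1_start", "bases1", "mapq1"),
            ("mate2_start", "bases2", "mapq2"),
        ):
            starts = group[start_col].to_numpy(dtype=np.int64)
            joined = "".join(group[base_col])
            codes = encode(joined)
            read_lengths = group[base_col].str.len().to_numpy(dtype=np.int64)
            if (read_lengths != read_lengths[0]).any() if len(read_lengths) else False:
                # variable-length reads: fall back to per-read accumulation
                offset = 0
                for s, l, q in zip(starts, read_lengths, group[mapq_col]):
                    idx = np.arange(s, s + l)
                    if idx[-1] >= length or s < 0:
                        raise ValueError(f"read outside contig {contig}")
                    c = codes[offset : offset + l]
                    np.add.at(pile.counts, (idx, c), 1)
                    np.add.at(pile.mapq_sums, (idx, c), int(q))
                    offset += l
                continue
            if len(starts) == 0:
                continue
            rl = int(read_lengths[0])
            positions = (starts[:, None] + np.arange(rl)).ravel()
            if positions.min(initial=0) < 0 or positions.max(initial=-1) >= length:
                raise ValueError(f"read outside contig {contig}")
            mapqs = np.repeat(group[mapq_col].to_numpy(dtype=np.int64), rl)
            np.add.at(pile.counts, (positions, codes), 1)
            np.add.at(pile.mapq_sums, (positions, codes), mapqs)
    return pileups


@dataclass
class CallOutcome:
    status: str  # snv | none | consensus_snv | tie_rejected | mapq_rejected
    record: SnvRecord | None = None


def call_site(
    site: PileupSite,
    mag_id: str = "",
    min_variant_reads: int = 2,
    min_variant_frequency: float = 0.05,
    consensus_snv_threshold: float = 0.40,
) -> CallOutcome:
    """Adjudicate one pileup site.

    The consensus is the most frequent base and must also carry the highest
    mean mapQ among observed bases (ties on count reject the site). The
    variant is the most frequent other base with >= ``min_variant_reads``
    support and frequency >= ``min_variant_frequency``; if its frequency
    reaches ``consensus_snv_threshold`` the site is a consensus SNV and is
    discarded.
    """
    counts = site.base_counts
    depth = int(counts.sum())
    if depth == 0:
        raise ValueError("call_site requires depth > 0")
    top = int(counts.argmax())
    if (counts == counts[top]).sum() > 1:
        return CallOutcome("tie_rejected")
    cons_mapq = site.mean_mapq(top)
    for b in range(4):
        if b != top and counts[b] > 0 and site.mean_mapq(b) > cons_mapq:
            return CallOutcome("mapq_rejected")
    others = [b for b in range(4) if b != top and counts[b] >= min_variant_reads]
    if not others:
        return CallOutcome("none")
    variant = max(others, key=lambda b: (counts[b], -b))  # count, then A<C<G<T
    freq = counts[variant] / depth
    if freq >= consensus_snv_threshold:
        return CallOutcome("consensus_snv")
    if freq < min_variant_frequency:
        return CallOutcome("none")
    return CallOutcome(
        "snv",
        SnvRecord(
            mag_id=mag_id,
            contig=site.contig,
            position=site.position,
            consensus_base=BASES[top],
            variant_base=BASES[variant],
            variant_frequency=float(freq),
            depth=depth,
        ),
    )


def call_snvs(
    pileups: Mapping[str, ContigPileup],
    mag: MagRecord,
    min_variant_reads: int = 2,
    min_variant_frequency: float = 0.05,
    consensus_snv_threshold: float = 0.40,
) -> tuple[list[SnvRecord], CallLog]:
    """Call every candidate site (>= min_variant_reads non-consensus support)."""
    log = CallLog()
    records: list[SnvRecord] = []
    for contig in sorted(pileups):
        pile = pileups[contig]
        counts = pile.counts
        # candidate sites: second-largest count reaches the support floor
        second = np.partition(counts, 2, axis=1)[:, 2]
        candidates = np.nonzero(second >= min_variant_reads)[0]
        for pos in candidates:
            log.n_candidate_sites += 1
            outcome = call_site(
                pile.site(int(pos)),
                mag_id=mag.mag_id,
                min_variant_reads=min_variant_reads,
                min_variant_frequency=min_variant_frequency,
                consensus_snv_threshold=consensus_snv_threshold,
            )
            if outcome.status == "snv":
                records.append(outcome.record)
                log.n_emitted += 1
            elif outcome.status == "consensus_snv":
                log.n_consensus_snv_discarded += 1
            elif outcome.status == "tie_rejected":
                log.n_tie_rejected += 1
            elif outcome.status == "mapq_rejected":
                log.n_mapq_rejected += 1
            else:
                log.n_below_frequency_floor += 1
    return records, log


def restrict_to_orfs(
    snvs: Sequence[SnvRecord], orfs: Sequence[Orf]
) -> tuple[list[SnvRecord], dict[str, int]]:
    """Keep SNVs inside ORFs, filling orf_id and the coding-strand offset.

    Genome-wide and in-ORF totals are both reported: the per-population SNV
    burden uses all SNVs, while shared-SNV analysis uses the in-ORF subset.
    """
    by_contig: dict[str, list[Orf]] = {}
    for o in orfs:
        by_contig.setdefault(o.contig, []).append(o)
    for lst in by_contig.values():
        lst.sort(key=lambda o: o.start)
    kept: list[SnvRecord] = []
    for snv in snvs:
        for orf in by_contig.get(snv.contig, ()):
            if orf.start <= snv.position < orf.end:
                offset = (snv.position - orf.start if orf.strand == "+"
                          else orf.end - 1 - snv.position)
                kept.append(replace(snv, orf_id=orf.orf_id, position_in_orf=offset))
                break
    return kept, {"total_snvs": len(snvs), "snvs_in_orfs": len(kept)}


def collate_snv_table(
    orf_snvs: Sequence[SnvRecord],
    mag: MagRecord,
    clusters: Mapping[tuple[str, str], str] | None = None,
) -> pd.DataFrame:
    """Collate the per-SNV table: site, frequencies, ORF location, the ORF
    nucleotide sequence, the inferred protein, and (when a protein clustering
    is supplied) the cluster each ORF belongs to."""
    orf_nt = mag.orf_nt_sequences()
    proteins = mag.protein_sequences()
    rows = []
    for s in orf_snvs:
        cluster = clusters.get((mag.mag_id, s.orf_id)) if clusters else s.cluster_id
        rows.append(
            {
                "mag_id": s.mag_id,
                "contig": s.contig,
                "position": s.position,
                "orf_id": s.orf_id,
                "position_in_orf": s.position_in_orf,
                "consensus_base": s.consensus_base,
                "variant_base": s.variant_base,
                "variant_frequency": s.variant_frequency,
                "depth": s.depth,
                "orf_nt_sequence": orf_nt.get(s.orf_id),
                "protein_sequence": proteins.get(s.orf_id),
                "cluster_id": cluster,
                "annotation": s.annotation,
            }
        )
    return pd.DataFrame(rows, columns=SNV_TABLE_COLUMNS)


def write_snv_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_snv_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"mag_id": str, "contig": str,
                                            "orf_id": str, "cluster_id": str,
                                            "annotation": str})
    return df.reindex(columns=SNV_TABLE_COLUMNS)


def call_pipeline(
    mag: MagRecord,
    pairs: pd.DataFrame,
    min_pair_identity: float = 0.90,
    min_mapq: int = 1,
    min_insert: int = 50,
    max_insert_factor: float = 3.0,
    min_variant_reads: int = 2,
    min_variant_frequency: float = 0.05,
    consensus_snv_threshold: float = 0.40,
) -> tuple[pd.DataFrame, dict[str, int], FilterLog, CallLog]:
    """Filter -> pileup -> call -> ORF restriction -> collated table."""
    retained, flog = filter_read_pairs(
        pairs, min_pair_identity, min_mapq, min_insert, max_insert_factor
    )
    pileups = build_pileup(retained, mag)
    snvs, clog = call_snvs(
        pileups, mag, min_variant_reads, min_variant_frequency, consensus_snv_threshold
    )
    orf_snvs, totals = restrict_to_orfs(snvs, mag.orfs)
    table = collate_snv_table(orf_snvs, mag)
    return table, totals, flog, clog
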