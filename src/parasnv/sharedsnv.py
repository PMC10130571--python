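"""Hierarchical shared-SNV identification across populations.

A "shared SNV at the same site" is an SNV present in two or more populations
at the corresponding (homologous) position of clustered ORFs; the stronger
level, "same substitution", additionally requires identical consensus and
variant bases in every participating population — the signal used to weigh
gene flow / shared ancestry against independent convergent mutation.

Sites shared by all six populations are flagged ancestral: polymorphisms
most parsimoniously present in the founding population.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .orthomap import ProteinCluster, SiteMap
from .simdata import MagRecord


@dataclass(frozen=True)
class Participant:
    mag_id: str
    orf_id: str
    contig: str
    position: int
    consensus_base: str
    variant_base: str


@dataclass
class SharedSnvRecord:
    cluster_id: str
    rep_position: int
    participants: list[Participant]
    ancestral: bool = False

    @property
    def mag_ids(self) -> list[str]:
        return sorted({p.mag_id for p in self.participants})

    @property
    def level(self) -> str:
        subs = {(p.consensus_base, p.variant_base) for p in self.participants}
        return "same_substitution" if len(subs) == 1 else "same_site"


def find_shared_snvs(
    snv_tables: Mapping[str, pd.DataFrame],
    clusters: Sequence[ProteinCluster],
    site_maps: Mapping[str, SiteMap],
) -> list[SharedSnvRecord]:
    """Group in-ORF SNVs by (cluster, representative coordinate).

    Every homologous site carrying an SNV in >= 2 populations yields one
    record. SNVs in singleton clusters cannot be shared and are skipped;
    an SNV in a multi-member cluster lacking a site map is an error.
    """
    orf_cluster: dict[tuple[str, str], str] = {}
    multi = set()
    for c in clusters:
        for m, o, _ in c.members:
            orf_cluster[(m, o)] = c.cluster_id
        if len(c.members) >= 2:
            multi.add(c.cluster_id)
    buckets: dict[tuple[str, int], list[Participant]] = {}
    for mag_id, table in snv_tables.items():
        for row in table.itertuples(index=False):
            if row.orf_id is None or (isinstance(row.orf_id, float) and np.isnan(row.orf_id)):
                continue
            key = (mag_id, row.orf_id)
            cid = orf_cluster.get(key)
            if cid is None or cid not in multi:
                continue
            if cid not in site_maps:
                raise KeyError(f"SNV in cluster {cid} but no site map supplied")
            rep_pos = site_maps[cid].rep_position(key, int(row.position_in_orf))
            if rep_pos is None:
                continue  # falls in an alignment gap: no homologous site
            buckets.setdefault((cid, rep_pos), []).append(
                Participant(mag_id, row.orf_id, row.contig, int(row.position),
                            row.consensus_base, row.variant_base)
            )
    records = []
    for (cid, rep_pos), parts in sorted(buckets.items()):
        if len({p.mag_id for p in parts}) >= 2:
            records.append(SharedSnvRecord(cid, rep_pos, sorted(parts, key=lambda p: p.mag_id)))
    return records


def flag_ancestral(records: Iterable[SharedSnvRecord], n_populations: int = 6
                   ) -> list[SharedSnvRecord]:
    """Records present in all populations, flagged as ancestral."""
    out = []
    for r in records:
        if len(r.mag_ids) == n_populations:
            r.ancestral = True
            out.append(r)
    return out


def _pair_counts(records: Sequence[SharedSnvRecord], a: str, b: str) -> tuple[int, int]:
    same_site = same_sub = 0
    for r in records:
        pa = [p for p in r.participants if p.mag_id == a]
        pb = [p for p in r.participants if p.mag_id == b]
        if not pa or not pb:
            continue
        same_site += 1
        if any(
            (x.consensus_base, x.variant_base) == (y.consensus_base, y.variant_base)
            for x in pa
            for y in pb
        ):
            same_sub += 1
    return same_site, same_sub


def _triplet_counts(records, trio):
    same_site = same_sub = 0
    for r in records:
        groups = [[p for p in r.participants if p.mag_id == m] for m in trio]
        if not all(groups):
            continue
        same_site += 1
        subs = [{(p.consensus_base, p.variant_base) for p in g} for g in groups]
        if set.intersection(*subs):
            same_sub += 1
    return same_site, same_sub


def default_triplets(mags: Mapping[str, MagRecord]) -> dict[str, tuple[str, ...]]:
    """Designated triplets: the two clade trios plus the abundant ("common")
    and rare trios."""
    labels = sorted(mags)
    trios = {}
    for clade in ("D", "S"):
        trio = tuple(l for l in labels if mags[l].clade == clade)
        if len(trio) == 3:
            trios[f"{clade}-clade"] = trio
    for cls, name in (("abundant", "common"), ("rare", "rare")):
        trio = tuple(l for l in labels if mags[l].abundance_class == cls)
        if len(trio) == 3:
            trios[name] = trio
    return trios


def summarize_groups(
    records: Sequence[SharedSnvRecord],
    mags: Mapping[str, MagRecord],
    triplets: Mapping[str, tuple[str, ...]] | None = None,
) -> pd.DataFrame:
    """Per-pair (all pairs) and per-designated-triplet shared-SNV counts.

    A triplet counts a site only when all three members carry an SNV there.
    ``n_same_substitution <= n_same_site`` by construction.
    """
    if triplets is None:
        triplets = default_triplets(mags)
    rows = []
    for a, b in itertools.combinations(sorted(mags), 2):
        site, sub = _pair_counts(records, a, b)
        rows.append({"group": f"{a},{b}", "kind": "pair", "mag_set": (a, b),
                     "n_same_site": site, "n_same_substitution": sub})
    for name, trio in triplets.items():
        site, sub = _triplet_counts(records, trio)
        rows.append({"group": f"{','.join(trio)} ({name})", "kind": "triplet",
                     "mag_set": tuple(trio), "n_same_site": site,
                     "n_same_substitution": sub})
    return pd.DataFrame(rows, columns=["group", "kind", "mag_set",
                                       "n_same_site", "n_same_substitution"])


def per_mag_snv_stats(
    snv_tables: Mapping[str, pd.DataFrame],
    totals: Mapping[str, Mapping[str, int]],
    mags: Mapping[str, MagRecord],
) -> pd.DataFrame:
    """Per-population SNV profile: totals, in-ORF counts, ORFs hit, mean
    SNVs per (hit) ORF — the inputs of the group comparisons."""
    rows = []
    for mag_id in sorted(mags):
        table = snv_tables[mag_id]
        orfs_hit = table["orf_id"].nunique()
        rows.append(
            {
                "mag_id": mag_id,
                "clade": mags[mag_id].clade,
                "depth_interval": mags[mag_id].depth_interval,
                "abundance_class": mags[mag_id].abundance_class,
                "total_snvs": int(totals[mag_id]["total_snvs"]),
                "snvs_in_orfs": int(totals[mag_id]["snvs_in_orfs"]),
                "orfs_with_snv": int(orfs_hit),
                "mean_snvs_per_orf": (len(table) / orfs_hit) if orfs_hit else 0.0,
            }
        )
    return pd.DataFrame(rows)


METRICS = ("total_snvs", "snvs_in_orfs", "orfs_with_snv", "mean_snvs_per_orf")


def compare_group_counts(
    stats_df: pd.DataFrame,
    welch: bool = False,
) -> pd.DataFrame:
    """Two-tailed t-tests of per-population SNV metrics across the standard
    groupings (abundance, clade, and each depth-interval pair).

    Student's equal-variance test by default; Welch available. Groups with
    fewer than two members yield an undefined (NaN) result row.
    """
    comparisons: list[tuple[str, pd.Series, str, str]] = []
    comparisons.append(("abundance", stats_df["abundance_class"], "abundant", "rare"))
    clades = sorted(stats_df["clade"].unique())
    if len(clades) == 2:
        comparisons.append(("clade", stats_df["clade"], clades[0], clades[1]))
    depths = sorted(stats_df["depth_interval"].unique())
    for da, db in itertools.combinations(depths, 2):
        comparisons.append(("depth", stats_df["depth_interval"], da, db))
    rows = []
    for grouping, labels, ga, gb in comparisons:
        xa_all = stats_df[labels == ga]
        xb_all = stats_df[labels == gb]
        for metric in METRICS:
            xa = xa_all[metric].to_numpy(dtype=float)
            xb = xb_all[metric].to_numpy(dtype=float)
            if len(xa) < 2 or len(xb) < 2:
                t = p = float("nan")
                defined = False
            else:
                t, p = stats.ttest_ind(xa, xb, equal_var=not welch)
                t, p = float(t), float(p)
                defined = True
            rows.append({"grouping": grouping, "group_a": ga, "group_b": gb,
                         "metric": metric, "t": t, "p": p, "defined": defined})
    return pd.DataFrame(rows)
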