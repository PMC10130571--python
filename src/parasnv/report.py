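"""Pipeline orchestration, per-population summaries and report rendering.

``run_pipeline`` drives the full analysis — simulate (or load) the six
populations, call SNVs per population against its own genome, cluster
proteins, identify shared SNVs, apply the convergence null model, compare
contig-pair ANI by shared-SNV status, and compare element identity matrices
— writing every stage table plus a manifest of content hashes under one run
directory. Reruns with the same configuration are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from . import anicompare, convergence, mgecompare, orthomap, sharedsnv, snvcall
from .simdata import (
    MagRecord,
    SimulationConfig,
    read_fasta,
    read_gff3,
    simulate_read_pairs,
    simulate_scenario,
    write_fasta,
    write_gff3,
    write_protein_fasta,
    write_read_pairs,
    write_truth,
)


def normalize_genome_size(assembled_size: float, completeness: float) -> float:
    """Estimated genome size: assembled size divided by completeness (the
    fraction of expected housekeeping genes recovered)."""
    if not (0 < completeness <= 1):
        raise ValueError("completeness must be in (0, 1]")
    if assembled_size < 0:
        raise ValueError("assembled size must be >= 0")
    return assembled_size / completeness


def mag_summary_table(
    mags: Mapping[str, MagRecord],
    stats_df: pd.DataFrame,
    abundances: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Per-population summary: abundance, normalized genome size, protein
    gene count and the SNV profile."""
    rows = []
    stats = stats_df.set_index("mag_id")
    for mag_id in sorted(mags):
        mag = mags[mag_id]
        rows.append(
            {
                "mag_id": mag_id,
                "clade": mag.clade,
                "depth_interval": mag.depth_interval,
                "abundance_pct": (abundances or {}).get(mag_id, np.nan),
                "abundance_class": mag.abundance_class,
                "assembled_size_bp": mag.genome_size,
                "completeness": mag.completeness,
                "estimated_genome_size_mbp": normalize_genome_size(
                    mag.genome_size, mag.completeness
                ) / 1e6,
                "n_protein_genes": len(mag.orfs),
                "total_snvs": int(stats.loc[mag_id, "total_snvs"]),
                "snvs_in_orfs": int(stats.loc[mag_id, "snvs_in_orfs"]),
                "orfs_with_snv": int(stats.loc[mag_id, "orfs_with_snv"]),
                "mean_snvs_per_orf": float(stats.loc[mag_id, "mean_snvs_per_orf"]),
            }
        )
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    config: SimulationConfig,
    outdir: str | Path,
    simulate: bool = True,
    inputs: Mapping[str, Mapping[str, Path]] | None = None,
    compute_ani: bool = True,
) -> dict:
    """Execute every stage and write the output bundle.

    With ``simulate=True`` the scenario generator provides all inputs; with
    ``simulate=False`` a per-population mapping of ``contigs`` (FASTA),
    ``orfs`` (GFF3) and ``pairs`` (read-pair TSV) paths must be supplied and
    is pre-flight checked before any stage runs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": [], "files": {}}

    if simulate:
        mags, truth, lineage = simulate_scenario(config)
        manifest["stages"].append("simulate")
        sim_dir = outdir / "simulated"
        sim_dir.mkdir(exist_ok=True)
        config.to_yaml(sim_dir / "config.yaml")
        for mag_id, mag in mags.items():
            write_fasta(mag.contigs, sim_dir / f"{mag_id}.contigs.fa")
            write_gff3(mag, sim_dir / f"{mag_id}.orfs.gff3")
            write_protein_fasta(mag, sim_dir / f"{mag_id}.proteins.fa")
        write_truth(truth, sim_dir)
        pairs_by_mag = {
            mag_id: simulate_read_pairs(mag, truth, config)
            for mag_id, mag in mags.items()
        }
        for mag_id, pairs in pairs_by_mag.items():
            write_read_pairs(pairs, sim_dir / f"{mag_id}.pairs.tsv")
        mge_records = mgecompare.records_from_truth(truth.mge_insertions, mags)
    else:
        if not inputs:
            raise FileNotFoundError("simulate=False requires per-population input paths")
        missing = [
            str(p)
            for spec in inputs.values()
            for p in spec.values()
            if not Path(p).exists()
        ]
        required = {"contigs", "orfs", "pairs"}
        for mag_id, spec in inputs.items():
            absent = required - set(spec)
            if absent:
                missing.extend(f"{mag_id}:{k}" for k in sorted(absent))
        if missing:
            raise FileNotFoundError("missing inputs: " + ", ".join(sorted(missing)))
        mags = {}
        pairs_by_mag = {}
        for mag_id, spec in inputs.items():
            mags[mag_id] = MagRecord(
                mag_id=mag_id,
                clade=mag_id.split("-")[0],
                depth_interval="unknown",
                abundance_class="abundant",
                contigs=read_fasta(spec["contigs"]),
                orfs=read_gff3(spec["orfs"]),
            )
            from .simdata import read_read_pairs

            pairs_by_mag[mag_id] = read_read_pairs(spec["pairs"])
        mge_records = []
        if any("mges" in spec for spec in inputs.values()):
            tables = [
                mgecompare.read_mge_table(spec["mges"])
                for spec in inputs.values()
                if "mges" in spec
            ]
            mge_records = mgecompare.records_from_table(pd.concat(tables), mags)

    # --- SNV calling, each population against its own genome
    snv_tables: dict[str, pd.DataFrame] = {}
    totals: dict[str, dict[str, int]] = {}
    coverage: dict[tuple[str, str], float] = {}
    for mag_id in sorted(mags):
        mag = mags[mag_id]
        table, tot, flog, clog = snvcall.call_pipeline(mag, pairs_by_mag[mag_id])
        snv_tables[mag_id] = table
        totals[mag_id] = tot
        for contig, seq in mag.contigs.items():
            sub = pairs_by_mag[mag_id]
            sub = sub[sub["contig"] == contig]
            nbases = (sub["bases1"].str.len().sum() + sub["bases2"].str.len().sum()) if len(sub) else 0
            coverage[(mag_id, contig)] = nbases / len(seq)
        snvcall.write_snv_table(table, outdir / f"snvs_{mag_id}.tsv")
        pd.DataFrame([dataclasses.asdict(flog) | dataclasses.asdict(clog)]).to_csv(
            outdir / f"filterlog_{mag_id}.tsv", sep="\t", index=False
        )
    manifest["stages"].append("snvcall")

    # --- protein clustering and site maps
    proteins = {
        (mag_id, orf_id): seq
        for mag_id, mag in mags.items()
        for orf_id, seq in mag.protein_sequences().items()
    }
    clusters = orthomap.cluster_proteins(proteins)
    orthomap.write_cluster_table(clusters, outdir / "protein_clusters.tsv")
    orf_nt = {
        (mag_id, orf_id): seq
        for mag_id, mag in mags.items()
        for orf_id, seq in mag.orf_nt_sequences().items()
    }
    site_maps = orthomap.build_site_maps(clusters, orf_nt)
    cluster_of = orthomap.orf_to_cluster(clusters)
    for mag_id in snv_tables:
        snv_tables[mag_id] = snv_tables[mag_id].assign(
            cluster_id=[
                cluster_of.get((mag_id, o)) if isinstance(o, str) else None
                for o in snv_tables[mag_id]["orf_id"]
            ]
        )
    manifest["stages"].append("orthomap")

    # --- shared SNVs, group summary, convergence
    records = sharedsnv.find_shared_snvs(snv_tables, clusters, site_maps)
    sharedsnv.flag_ancestral(records, n_populations=len(mags))
    summary = sharedsnv.summarize_groups(records, mags)
    table3 = convergence.convergence_table(summary)
    table3.to_csv(outdir / "convergence_table.tsv", sep="\t", index=False)
    stats_df = sharedsnv.per_mag_snv_stats(snv_tables, totals, mags)
    ttests = sharedsnv.compare_group_counts(stats_df)
    ttests.to_csv(outdir / "group_ttests.tsv", sep="\t", index=False)
    summary_tbl = mag_summary_table(mags, stats_df)
    summary_tbl.to_csv(outdir / "mag_summary.tsv", sep="\t", index=False)
    manifest["stages"] += ["sharedsnv", "convergence"]

    # --- ANI by shared-SNV status
    ani_rows = []
    if compute_ani:
        shared_pairs = anicompare.label_shared_contigs(records)
        mag_ids = sorted(mags)
        for i, a in enumerate(mag_ids):
            for b in mag_ids[i + 1 :]:
                ptable = anicompare.build_contig_pair_table(
                    mags[a], mags[b], shared_pairs, coverage
                )
                cmp = anicompare.compare_groups(ptable)
                ani_rows.append(
                    {
                        "mag_pair": f"{a},{b}",
                        "mean_ani_shared": cmp.mean_ani_shared,
                        "mean_ani_unshared": cmp.mean_ani_unshared,
                        "n_shared": cmp.n_shared,
                        "n_unshared": cmp.n_unshared,
                        "coverage_p": cmp.coverage_p,
                        "length_p": cmp.length_p,
                    }
                )
        pd.DataFrame(ani_rows).to_csv(outdir / "ani_groups.tsv", sep="\t", index=False)
        manifest["stages"].append("anicompare")

    # --- element identity matrices
    congruence: dict[str, str] = {}
    clades = {mag_id: mag.clade for mag_id, mag in mags.items()}
    for name in sorted({r.mge_name for r in mge_records}):
        recs = [r for r in mge_records if r.mge_name == name]
        if len(recs) < 2:
            continue
        matrix = mgecompare.mge_identity_matrix(recs, mag_order=sorted(mags))
        mgecompare.write_identity_matrix(matrix, outdir / f"mge_identity_{name}.tsv")
        congruence[name] = mgecompare.clade_congruence(matrix, clades)
    if congruence:
        pd.DataFrame(
            [{"mge_name": k, "clade_congruence": v} for k, v in sorted(congruence.items())]
        ).to_csv(outdir / "mge_congruence.tsv", sep="\t", index=False)
        manifest["stages"].append("mgecompare")

    # --- report + manifest
    report = render_reports(summary_tbl, table3, pd.DataFrame(ani_rows), congruence)
    (outdir / "report.md").write_text(report)
    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["files"][str(path.relative_to(outdir))] = _sha256(path)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def render_reports(
    mag_summary: pd.DataFrame | None,
    convergence_table: pd.DataFrame | None,
    ani_groups: pd.DataFrame | None,
    congruence: Mapping[str, str] | None,
) -> str:
    """Markdown report with population-summary, shared-SNV/convergence, ANI
    and element-congruence sections. Sub-unit convergent expectations are
    rendered "<1 (value)" alongside the numeric value."""
    lines = ["# Shared-SNV analysis report", ""]
    if mag_summary is None or not len(mag_summary):
        lines.append("no data")
        return "\n".join(lines) + "\n"
    lines.append("## Population summaries")
    lines.append("```\n" + mag_summary.to_string(index=False) + "\n```")
    lines.append("")
    if convergence_table is not None and len(convergence_table):
        lines.append("## Shared SNVs and convergent expectations")
        tbl = convergence_table.copy()
        tbl["expected"] = [
            f"<1 ({v:.4g})" if 0 < v < 1 else f"{v:.2f}"
            for v in tbl["expected_convergent"]
        ]
        lines.append(
            "```\n"
            + tbl[["group", "kind", "n_same_site", "n_same_substitution",
                   "expected", "evidence"]].to_string(index=False)
            + "\n```"
        )
        lines.append("")
    if ani_groups is not None and len(ani_groups):
        lines.append("## Contig-pair ANI by shared-SNV status")
        lines.append("```\n" + ani_groups.to_string(index=False) + "\n```")
        lines.append("")
    if congruence:
        lines.append("## Mobile element clade congruence")
        for name, verdict in sorted(congruence.items()):
            lines.append(f"- {name}: {verdict}")
        lines.append("")
    return "\n".join(lines) + "\n"
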