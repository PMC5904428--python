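"""End-to-end orchestration: validate -> distances -> geography ->
haplotypes -> network -> richness, with a consolidated summary JSON.

Presentation rounding is centralised here: percentages at one decimal,
kilometres and richness estimates at the nearest integer; all exported
long-format tables keep full precision.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import alignment_io, distances, geography, haplotypes, network, richness

__all__ = ["RunConfig", "run_full_analysis", "pct", "km"]


def pct(fraction: float) -> str:
    """Render a fraction as a percentage at one decimal, as in the tables."""
    return f"{100 * fraction:.1f} %"


def km(value: float) -> int:
    return int(round(value))


@dataclass
class RunConfig:
    alignment_path: str | Path
    metadata_path: str | Path
    out_dir: str | Path
    ingroup_taxon: str
    code: str = "invertebrate-mito"
    frame: int = 0
    alpha: float = 0.95
    fixed_limit: int | None = None
    richness_runs: int = 100
    target_fraction: float | None = None
    seed: int = 0


def run_full_analysis(config: RunConfig) -> dict:
    """Run every stage, write its table, and return the summary dict.

    Stage failures abort with a diagnostic naming the stage; partially
    written outputs are removed on failure.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed}
    try:
        _run_stages(config, out, summary)
    except Exception as exc:
        shutil.rmtree(out, ignore_errors=True)
        raise RuntimeError(f"stage {summary.get('_stage', '?')!r} failed: {exc}") from exc
    summary.pop("_stage", None)
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


def _run_stages(config: RunConfig, out: Path, summary: dict) -> None:
    summary["_stage"] = "validate"
    aln = alignment_io.read_alignment(config.alignment_path)
    meta = alignment_io.read_metadata(config.metadata_path)
    ds = alignment_io.join_dataset(aln, meta, config.ingroup_taxon)
    stops = alignment_io.screen_reading_frame(aln, config.code, config.frame)
    summary["validate"] = {
        "records": len(aln),
        "length": aln.length,
        "ingroup": len(ds.ingroup_ids),
        "records_with_stop_codons": sum(1 for v in stops.values() if v > 0),
    }

    summary["_stage"] = "distances"
    dm = distances.distance_matrix(aln)
    dm.pair_table().to_csv(out / "pairs.tsv", sep="\t", index=False)
    dm.to_square_frame().to_csv(out / "distance_matrix.tsv", sep="\t")
    ingroup = ds.ingroup_ids
    summ = distances.specimen_summary(dm, ingroup)
    pd.DataFrame([s.__dict__ for s in summ]).to_csv(
        out / "specimen_summary.tsv", sep="\t", index=False
    )
    dist_block = {
        "pairs_ingroup": len(ingroup) * (len(ingroup) - 1) // 2,
        "max_intraspecific": float(
            max(dm.value(a, b) for i, a in enumerate(ingroup) for b in ingroup[i + 1 :])
        ) if len(ingroup) > 1 else None,
    }
    outgroup_present = len(ingroup) < len(aln)
    if outgroup_present and len(ingroup) >= 2:
        gap = distances.barcoding_gap(dm, ds.taxa, config.ingroup_taxon)
        dist_block.update(
            {
                "min_interspecific": gap.min_interspecific,
                "min_interspecific_by_taxon": gap.min_interspecific_by_taxon,
                "gap_present": gap.gap_present,
            }
        )
    summary["distances"] = dist_block

    summary["_stage"] = "geography"
    have_coords = [
        i for i in ingroup
        if ds.by_id[i].latitude is not None and ds.by_id[i].longitude is not None
    ]
    if len(have_coords) >= 3:
        geo = geography.pairwise_geo_table(ds, dm)
        geo.to_csv(out / "geo_pairs.tsv", sep="\t", index=False)
        trend = geography.ibd_trend(geo)
        summary["geography"] = {
            "pairs": int(len(geo)),
            "max_km": float(geo["geo_km"].max()),
            "slope_pct_per_km": 100 * trend.slope,
            "r_squared": trend.r_squared,
        }
    else:
        summary["geography"] = {"pairs": 0}

    summary["_stage"] = "haplotypes"
    ingroup_aln = ds.ingroup_alignment()
    table = haplotypes.collapse_haplotypes(ingroup_aln)
    table.to_frame().to_csv(out / "haplotypes.tsv", sep="\t", index=False)
    stats = haplotypes.diversity_stats(ingroup_aln, table, config.code, config.frame)
    freq = haplotypes.region_frequency_matrix(table, ds.metadata)
    freq.to_csv(out / "haplotype_by_region.tsv", sep="\t")
    haplotypes.region_summary(table, ds.metadata, dm).to_csv(
        out / "region_summary.tsv", sep="\t", index=False
    )
    haplotypes.write_popart_nexus(table, freq, out / "haplotypes_traits.nex")
    nonsyn = haplotypes.collapse_nonsynonymous_only(
        ingroup_aln, config.code, config.frame
    )
    abundances = table.abundances
    summary["haplotypes"] = {
        "s_obs": table.s_obs,
        "singletons": int((abundances == 1).sum()),
        "segregating_sites": stats.segregating_sites,
        "total_mutations": stats.total_mutations,
        "haplotype_diversity": stats.haplotype_diversity,
        "nucleotide_diversity": stats.nucleotide_diversity,
        "synonymous_changes": stats.synonymous_changes,
        "replacement_changes": stats.replacement_changes,
        "nonsynonymous_only_haplotypes": nonsyn.s_obs,
        "single_region_haplotypes": int((freq.gt(0).sum(axis=1) == 1).sum()),
    }

    summary["_stage"] = "network"
    limit = (
        network.ParsimonyLimit(J=config.fixed_limit, alpha=config.alpha, L=aln.length)
        if config.fixed_limit is not None
        else network.parsimony_limit(len(table.retained_sites), config.alpha)
    )
    net = network.build_tcs_network(table, limit, freq)
    network.export_network(net, out / "network_edges.tsv", out / "network.graphml")
    summary["network"] = {
        "parsimony_limit": limit.J,
        "nodes": net.number_of_nodes(),
        "observed_nodes": table.s_obs,
        "median_nodes": net.number_of_nodes() - table.s_obs,
        "edges": net.number_of_edges(),
        "components": nx.number_connected_components(net),
    }

    summary["_stage"] = "richness"
    est = richness.chao1(abundances)
    curve = richness.rarefaction_curve(abundances)
    pd.DataFrame(curve).to_csv(out / "rarefaction.tsv", sep="\t", index=False)
    runs = richness.accumulation_curves(
        abundances, runs=config.richness_runs, rng=config.seed
    )
    np.savetxt(out / "accumulation_runs.tsv", runs, fmt="%d", delimiter="\t")
    needed = richness.samples_needed(
        abundances, target_fraction=config.target_fraction
    )
    try:
        ace_value = richness.ace(abundances)
    except ValueError:
        ace_value = None
    summary["richness"] = {
        "s_obs": est.s_obs,
        "chao1": est.s_chao1,
        "chao1_rounded": int(round(est.s_chao1)),
        "ci_low": est.ci_low,
        "ci_high": est.ci_high,
        "ace": ace_value,
        "samples_needed": needed,
    }
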