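"""Full-analysis orchestration: stats -> distance/tree -> PCoA -> AMOVA ->
structure -> marker selection, driven by one TOML config and one global seed.
"""

from __future__ import annotations

import json
import logging
import tomllib
from dataclasses import dataclass
from pathlib import Path

from capspop import __version__
from capspop.amova import amova_codominant, permute_fst
from capspop.distance_clustering import distance_matrix, to_newick, upgma
from capspop.diversity_stats import (
    compute_all_locus_stats,
    stats_table,
    summarize_panel,
)
from capspop.genotype_data import (
    GenotypeDataError,
    read_genotype_table,
    read_marker_table,
)
from capspop.marker_selection import accumulation_curve, greedy_minimal_marker_set
from capspop.ordination import pcoa
from capspop.structure_admixture import (
    classify_membership,
    evanno_delta_k,
    run_admixture_gibbs,
)

logger = logging.getLogger(__name__)

# fixed per-stage seed offsets derived from the one global seed
STAGE_SEED_OFFSETS = {
    "amova": 101,
    "structure": 202,
    "select_markers": 303,
}

DEFAULT_STAGES = ("stats", "distance", "tree", "pcoa", "amova", "structure", "select_markers")


@dataclass
class PipelineConfig:
    genotype_table: str
    out_dir: str
    seed: int = 0
    marker_table: str | None = None
    population_column: str | None = None  # path to a two-column label TSV
    stages: tuple[str, ...] = DEFAULT_STAGES
    amova_permutations: int = 1000
    structure_k_min: int = 1
    structure_k_max: int = 4
    structure_replicates: int = 3
    structure_burn_in: int = 500
    structure_iters: int = 2000
    admix_threshold: float = 0.7
    accumulation_samples: int = 50

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise GenotypeDataError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def stage_seed(self, stage: str) -> int:
        return self.seed + STAGE_SEED_OFFSETS.get(stage, 0)


def _read_population_labels(path: str) -> dict[str, str]:
    labels = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 2 and parts[0] and parts[0] != "accession":
                labels[parts[0]] = parts[1]
    return labels


def run_full_analysis(cfg: PipelineConfig) -> dict:
    """Run every enabled stage, writing per-stage files plus summary.json."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gm = read_genotype_table(cfg.genotype_table)
    defs = read_marker_table(cfg.marker_table) if cfg.marker_table else None
    if cfg.population_column:
        label_map = _read_population_labels(cfg.population_column)
        gm = gm.with_population_labels([label_map[a] for a in gm.accession_ids])

    summary: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "n_accessions": gm.n_accessions,
        "n_markers": gm.n_markers,
        "stages": list(cfg.stages),
    }
    stats = None
    dm = None

    for stage in cfg.stages:
        logger.info("pipeline stage: %s", stage)
        try:
            if stage == "stats":
                stats = compute_all_locus_stats(gm)
                stats_table(stats).to_csv(out / "locus_stats.tsv", sep="\t", index=False)
                panel = summarize_panel(stats, defs)
                summary["stats"] = {
                    "n_polymorphic": panel.n_polymorphic,
                    "n_monomorphic": panel.n_monomorphic,
                    "mean_all": panel.mean_all,
                    "mean_polymorphic": panel.mean_polymorphic,
                    "gd_by_class": panel.gd_by_class,
                }
            elif stage == "distance":
                dm = distance_matrix(gm)
                dm.to_dataframe().to_csv(out / "nei_distance.tsv", sep="\t")
            elif stage == "tree":
                dm = dm if dm is not None else distance_matrix(gm)
                newick = to_newick(upgma(dm))
                (out / "upgma.nwk").write_text(newick + "\n")
                summary["tree"] = {"newick_file": "upgma.nwk"}
            elif stage == "pcoa":
                dm = dm if dm is not None else distance_matrix(gm)
                res = pcoa(dm)
                res.to_dataframe().to_csv(out / "pcoa_coordinates.tsv", sep="\t")
                summary["pcoa"] = {
                    "eigenvalues": res.eigenvalues.tolist(),
                    "percent_variance": res.percent_variance.tolist(),
                }
            elif stage == "amova":
                if gm.population_labels is None:
                    raise GenotypeDataError("amova stage requires population labels")
                result = amova_codominant(gm)
                p = permute_fst(
                    gm, result, n_perm=cfg.amova_permutations, seed=cfg.stage_seed("amova")
                )
                result.p_value, result.n_permutations = p, cfg.amova_permutations
                result.to_dataframe().to_csv(out / "amova.tsv", sep="\t", index=False)
                summary["amova"] = {"f_st": result.f_st, "p_value": p}
            elif stage == "structure":
                runs_by_k: dict[int, list[float]] = {}
                best_runs = {}
                for k in range(cfg.structure_k_min, cfg.structure_k_max + 1):
                    runs_by_k[k] = []
                    for rep in range(cfg.structure_replicates):
                        run = run_admixture_gibbs(
                            gm,
                            k,
                            burn_in=cfg.structure_burn_in,
                            n_iter=cfg.structure_iters,
                            seed=cfg.stage_seed("structure") + 1000 * k + rep,
                        )
                        runs_by_k[k].append(run.ln_pd)
                        if k not in best_runs or run.ln_pd > best_runs[k].ln_pd:
                            best_runs[k] = run
                table = evanno_delta_k(runs_by_k)
                table.to_dataframe().to_csv(out / "evanno.tsv", sep="\t", index=False)
                best = best_runs[table.optimal_k]
                best.to_q_dataframe().to_csv(out / "q_matrix.tsv", sep="\t")
                membership = classify_membership(best, cfg.admix_threshold)
                summary["structure"] = {
                    "optimal_k": table.optimal_k,
                    "membership": membership,
                }
            elif stage == "select_markers":
                stats = stats if stats is not None else compute_all_locus_stats(gm)
                sel = greedy_minimal_marker_set(gm, stats)
                curve = accumulation_curve(
                    gm, r=cfg.accumulation_samples, seed=cfg.stage_seed("select_markers")
                )
                with open(out / "accumulation_curve.tsv", "w") as fh:
                    fh.write("n_loci\tmean_mlg\n")
                    for n, mean in zip(curve.subset_sizes, curve.mean_curve):
                        fh.write(f"{n}\t{mean}\n")
                if sel.selected:
                    sub = gm.subset_markers(sel.selected)
                    (out / "selected_subset.nwk").write_text(
                        to_newick(upgma(distance_matrix(sub))) + "\n"
                    )
                summary["selection"] = {
                    "selected_markers": sel.selected,
                    "step_counts": sel.step_counts,
                    "complete": sel.complete,
                }
            else:
                raise GenotypeDataError(f"unknown stage {stage!r}")
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary
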