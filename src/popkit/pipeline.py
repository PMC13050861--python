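"""End-to-end orchestration: simulate/ingest -> diversity -> tree ->
structure -> AMOVA -> association -> trait report, with a manifest.

One config (YAML/JSON/dict) drives every stage; a single global seed makes
the whole run reproducible, and the manifest records inputs, parameters and
SHA-256 hashes of every artifact so reruns can be compared byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import admixture, amova, association, distance, genotypes, simulate, traits

log = logging.getLogger("popkit")

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    out_dir: str = "popkit_out"
    seed: int = 0
    # inputs: either simulate, or paths to band matrix / trait TSVs
    band_matrix: str | None = None
    trait_table: str | None = None
    simulate: bool = True
    sim: dict = field(default_factory=dict)  # SimulationConfig overrides
    # stage toggles
    run_diversity: bool = True
    run_tree: bool = True
    run_structure: bool = True
    run_amova: bool = True
    run_association: bool = True
    run_traits: bool = True
    # stage parameters (defaults follow the study protocol)
    tree_distance: str = "nei_li"
    cut_k: int = 3
    k_min: int = 1
    k_max: int = 10
    n_runs: int = 20
    burnin: int = 10_000
    iters: int = 100_000
    n_perm: int = 999
    n_pc: int = 5
    fdr_level: float = 0.05
    amova_labels: str = "tree"  # "tree" | "structure"

    def validate(self) -> None:
        if not self.simulate:
            for path, name in ((self.band_matrix, "band_matrix"),):
                if path is None or not Path(path).exists():
                    raise FileNotFoundError(f"required input {name!r} not resolvable: {path}")
            if self.run_association or self.run_traits:
                if self.trait_table is None or not Path(self.trait_table).exists():
                    raise FileNotFoundError(f"trait_table not resolvable: {self.trait_table}")
        if self.run_amova and self.amova_labels == "structure" and not self.run_structure:
            raise ValueError("amova_labels='structure' requires the structure stage")


def load_config(path: str | Path) -> PipelineConfig:
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    return PipelineConfig(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def save(name: str, writer) -> Path:
        path = out / name
        writer(path)
        artifacts[name] = _sha256(path)
        return path

    log.info("pipeline start: seed=%d out=%s", config.seed, out)
    truth = None
    if config.simulate:
        sim_cfg = simulate.SimulationConfig(seed=config.seed, **config.sim)
        matrix, trait_table, truth = simulate.simulate_dataset(sim_cfg)
        save("band_matrix.tsv", lambda p: genotypes.write_band_matrix(matrix, p))
        save("traits.tsv", lambda p: traits.write_trait_table(trait_table, p))
        truth_blob = {
            "true_Q": truth.true_Q.tolist(),
            "true_band_freqs": truth.true_band_freqs.tolist(),
            "causal_band_ids": truth.causal_band_ids,
            "true_effects": truth.true_effects,
        }
        save("truth.json", lambda p: p.write_text(json.dumps(truth_blob)))
    else:
        matrix = genotypes.read_band_matrix(config.band_matrix)
        trait_table = (
            traits.read_trait_table(config.trait_table) if config.trait_table else None
        )
    matrix.validate_qc()

    if config.run_diversity:
        report = genotypes.dataset_diversity_report(matrix)
        save("diversity.tsv", lambda p: report.to_csv(p, sep="\t"))
        log.info(
            "diversity: total Na=%d, mean alleles/marker=%.1f",
            report.attrs["total_Na"], report.attrs["mean_alleles_per_marker"],
        )

    labels = None
    if config.run_tree:
        D_tree = distance.pairwise_distance_matrix(matrix, config.tree_distance)
        save("distance_tree.tsv", D_tree.write)
        tree = distance.upgma(D_tree)
        save("dendrogram.nwk", lambda p: p.write_text(tree.to_newick()))
        labels = distance.cut_tree(tree, config.cut_k)
        save("tree_groups.tsv", lambda p: labels.to_csv(p, sep="\t"))

    q_labels = None
    if config.run_structure:
        sweep = admixture.structure_sweep(
            matrix,
            range(config.k_min, config.k_max + 1),
            n_runs=config.n_runs,
            burnin=config.burnin,
            iters=config.iters,
            seed=config.seed,
        )
        save("structure_sweep.tsv", lambda p: sweep.table.to_csv(p, sep="\t", index=False))
        evanno, k_star = admixture.evanno_delta_k(sweep)
        save("evanno.tsv", lambda p: evanno.to_csv(p, sep="\t"))
        q_best = sweep.q_by_k[k_star]
        save("q_matrix.tsv", lambda p: q_best.to_frame().to_csv(p, sep="\t"))
        q_labels = q_best.assignments()
        log.info("structure: selected K*=%d", k_star)

    if config.run_amova:
        D_j = distance.pairwise_distance_matrix(matrix, "jaccard")
        save("distance_jaccard.tsv", D_j.write)
        if config.amova_labels == "structure" and q_labels is not None:
            grp = q_labels
        else:
            if labels is None:
                raise ValueError("AMOVA needs group labels from the tree or structure stage")
            if config.amova_labels == "structure":
                log.warning("structure labels unavailable; substituting tree-cut labels")
            grp = labels.to_numpy()
        res = amova.amova(D_j, grp, n_perm=config.n_perm, seed=config.seed)
        save("amova.tsv", lambda p: res.to_frame().to_csv(p, sep="\t", index=False))
        pw = amova.pairwise_fst(D_j, grp)
        save("pairwise_fst.tsv", lambda p: pw.to_csv(p, sep="\t"))
        log.info("amova: Fst=%.3f p=%s", res.Fst, res.p_perm)

    if config.run_association and trait_table is not None:
        results = association.association_study(trait_table, matrix, n_pc=config.n_pc)
        save("associations.tsv", lambda p: results.to_csv(p, sep="\t", index=False))
        sig = association.report_associations(results, fdr_level=config.fdr_level)
        save("associations_significant.tsv", lambda p: sig.to_csv(p, sep="\t", index=False))

    if config.run_traits and trait_table is not None:
        summ = traits.trait_summary(trait_table)
        save("trait_summary.tsv", lambda p: summ.to_csv(p, sep="\t"))
        pca = traits.mixed_pca(trait_table)
        save("trait_pca_scores.tsv", lambda p: pca.scores.to_csv(p, sep="\t"))
        save(
            "trait_pca_variance.tsv",
            lambda p: p.write_text(
                "component\tpercent_variance\n"
                + "\n".join(f"PC{i + 1}\t{v:.6f}" for i, v in enumerate(pca.percent_variance))
            ),
        )
        corr, flags = traits.trait_correlations(trait_table)
        save("trait_correlations.tsv", lambda p: corr.to_csv(p, sep="\t"))
        save("trait_correlation_flags.tsv", lambda p: flags.to_csv(p, sep="\t"))

    manifest = {
        "config": asdict(config),
        "seed": config.seed,
        "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
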