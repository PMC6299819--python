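"""End-to-end orchestration: profile -> weight -> asr -> distcmp.

A single YAML-configured run executes the stages in order, writes every stage
table, and records a manifest (parameters, input checksums, per-stage record
counts) so a run is auditable and reruns on identical inputs are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional

import yaml

from . import __version__
from . import asr as asr_mod
from . import profiles as prof
from . import treedist, weighting
from .trees import read_tree, write_tree

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)

CONFIG_SCHEMA_VERSION = 1


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Inputs, thresholds, and output location of one pipeline run.

    ``domain_trees`` maps a domain name (Competence, DUF4131, Lactamase_B) to
    a Newick path; species_tree leaves and domain-tree leaves are strain ids
    from the metadata table. All thresholds default to the published values.
    """

    domtbl: str = ""
    blast: str = ""
    metadata: str = ""
    species_tree: str = ""
    domain_trees: Dict[str, str] = field(default_factory=dict)
    out_dir: str = "results/run"
    evalue_max: float = 1e-5
    model_coverage_min: float = 0.70
    qcov_min: float = 0.30
    identity_min: float = 0.60
    z_threshold: float = 3.0
    seed: int = 0
    schema_version: int = CONFIG_SCHEMA_VERSION

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        version = raw.pop("schema_version", CONFIG_SCHEMA_VERSION)
        if version != CONFIG_SCHEMA_VERSION:
            raise ValueError(f"unsupported config schema_version {version}")
        return cls(**raw)

    def validate(self) -> None:
        if not (0 < self.model_coverage_min <= 1):
            raise ValueError("model_coverage_min outside (0, 1]")
        if not (0 <= self.qcov_min <= 1 and 0 <= self.identity_min <= 1):
            raise ValueError("rescue thresholds outside [0, 1]")
        if self.evalue_max < 0 or self.z_threshold <= 0:
            raise ValueError("bad threshold value")
        paths = [self.domtbl, self.metadata]
        if self.blast:
            paths.append(self.blast)
        if self.species_tree:
            paths.append(self.species_tree)
        paths.extend(self.domain_trees.values())
        missing = [p for p in paths if p and not os.path.exists(p)]
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")
        if not self.domtbl or not self.metadata:
            raise ValueError("domtbl and metadata inputs are required")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages; return (and write) the run manifest."""
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    out = lambda name: os.path.join(config.out_dir, name)
    manifest: dict = {
        "domarch_version": __version__,
        "parameters": asdict(config),
        "inputs": {},
        "stages": {},
        "outputs": [],
    }
    for path in [config.domtbl, config.blast, config.metadata, config.species_tree,
                 *config.domain_trees.values()]:
        if path:
            manifest["inputs"][path] = _sha256(path)

    # --- profile stage -----------------------------------------------------
    stage = "profile"
    try:
        hits = prof.parse_domtblout(config.domtbl)
        kept = prof.filter_domain_hits(
            hits, evalue_max=config.evalue_max,
            model_coverage_min=config.model_coverage_min,
        )
        profiles = prof.build_profiles(kept)
        nuc_hits = prof.parse_blast_tab(config.blast) if config.blast else []
        nuc_hits = [
            h for h in nuc_hits
            if prof.rescue_filter(
                h, evalue_max=config.evalue_max,
                qcov_min=config.qcov_min, identity_min=config.identity_min,
            )
        ]
        metadata = prof.read_metadata(config.metadata)
        states = prof.strain_state_table(profiles, nuc_hits, metadata)
        states_df = prof.states_to_frame(states)
        _write_tsv(states_df, out("strain_states.tsv"))
        report = prof.census_report(states, profiles)
        with open(out("census.json"), "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        manifest["stages"][stage] = {
            "hits_total": len(hits),
            "hits_kept": len(kept),
            "proteins": len(profiles),
            "nucleotide_hits_passing": len(nuc_hits),
            "strains": len(states),
        }
        manifest["outputs"] += [out("strain_states.tsv"), out("census.json")]
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise PipelineError(stage, exc) from exc

    # --- weighting stage ---------------------------------------------------
    stage = "weight"
    try:
        rel = weighting.relative_counts(states)
        _write_tsv(rel, out("relative_counts.tsv"))
        taxon_map = dict(zip(metadata["species"], metadata["taxon"]))
        freqs = weighting.taxon_frequencies(rel, taxon_map)
        _write_tsv(freqs, out("taxon_frequencies.tsv"))
        manifest["stages"][stage] = {
            "species": int(rel["species"].nunique()) if len(rel) else 0,
            "taxa": int(freqs["taxon"].nunique()) if len(freqs) else 0,
        }
        manifest["outputs"] += [
            out("relative_counts.tsv"), out("taxon_frequencies.tsv"),
        ]
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    # --- ancestral-state stage --------------------------------------------
    if config.species_tree:
        stage = "asr"
        try:
            tree = read_tree(config.species_tree)
            leaf_states = asr_mod.asr_leaf_states(states)
            tip_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
            leaf_states = {k: v for k, v in leaf_states.items() if k in tip_labels}
            fit = asr_mod.fit_er_rate(tree, leaf_states)
            model = asr_mod.ErModel(mu=fit.mu_hat)
            posteriors = asr_mod.marginal_posteriors(tree, leaf_states, model)
            table = asr_mod.posterior_table(tree, posteriors)
            _write_tsv(table, out("asr_posteriors.tsv"))
            annotated = asr_mod.annotate_map_states(tree, posteriors)
            write_tree(annotated, out("asr_annotated.nwk"))
            manifest["stages"][stage] = {
                "mu_hat": fit.mu_hat,
                "loglik": fit.loglik,
                "rate_at_bound": fit.rate_at_bound,
                "internal_nodes": len(table),
            }
            manifest["outputs"] += [
                out("asr_posteriors.tsv"), out("asr_annotated.nwk"),
            ]
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(stage, exc) from exc

    # --- distance-comparison stage ----------------------------------------
    if config.domain_trees:
        stage = "distcmp"
        try:
            species_tree = read_tree(config.species_tree)
            species_dm = treedist.cophenetic(species_tree)
            cdcp = {s.strain_id for s in states if s.state != "NC"}
            species_dm = treedist.normalize_species(species_dm, cdcp)
            state_map = {s.strain_id: s.state for s in states}
            fit_rows = []
            all_pairs: Dict[str, List[treedist.PairRecord]] = {}
            for domain in sorted(config.domain_trees):
                dtree = read_tree(config.domain_trees[domain])
                ddm = treedist.normalize_domain(treedist.cophenetic(dtree))
                groups = treedist.pair_subsets(species_dm, ddm, state_map, domain)
                for subset in sorted(groups):
                    pairs = groups[subset]
                    if len(pairs) >= 3:
                        fit = treedist.fit_and_flag(pairs, config.z_threshold)
                        fit_rows.append(
                            {
                                "subset": subset,
                                "slope": fit.slope,
                                "intercept": fit.intercept,
                                "r_squared": fit.r_squared,
                                "n_pairs": fit.n_pairs,
                                "n_low": sum(p.outlier_flag == "low" for p in pairs),
                                "n_high": sum(p.outlier_flag == "high" for p in pairs),
                            }
                        )
                    all_pairs[subset] = pairs
            import pandas as pd

            _write_tsv(treedist.pairs_to_frame(all_pairs), out("pair_records.tsv"))
            _write_tsv(pd.DataFrame(fit_rows), out("regression_fits.tsv"))
            manifest["stages"][stage] = {
                "subsets_fitted": len(fit_rows),
                "pairs_total": sum(len(v) for v in all_pairs.values()),
            }
            manifest["outputs"] += [
                out("pair_records.tsv"), out("regression_fits.tsv"),
            ]
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(stage, exc) from exc

    with open(out("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    for path in manifest["outputs"]:
        assert os.path.exists(path)
    return manifest
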