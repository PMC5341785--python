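"""End-to-end composition: simulate -> count -> screen -> validate -> summarize.

Every run writes its full parameter set to ``params.yaml`` in the output
directory, so a run is reproducible from its artifacts alone; with a fixed
seed the artifact directory is byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .counts import OverlapPolicy, build_pileup, dedup_fragments
from .screen import ScreenConfig, run_screen
from .simulate import SimulationConfig, simulate_amplicon, simulate_patient_cohort
from .validate import results_table, validate_candidate, validation_summary

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Flat view of all stage parameters, with user-set provenance."""

    simulation: SimulationConfig = SimulationConfig()
    screen: ScreenConfig = ScreenConfig()
    policy: OverlapPolicy = OverlapPolicy.COUNT_ONCE
    amplicon_depth: int = 100_000
    validation_alpha: float = 0.001
    validation_bonferroni: bool = True
    write_reads: bool = False
    user_set: frozenset = frozenset()

    def flat(self) -> dict:
        out = {}
        for section, obj in (("simulate", self.simulation), ("screen", self.screen)):
            for f in fields(obj):
                v = getattr(obj, f.name)
                if f.name == "clone_spec":
                    v = [[c.subpopulation, c.allelic_fraction, c.count] for c in v]
                elif f.name == "subpopulations":
                    v = list(v)
                out[f"{section}.{f.name}"] = v
        out["policy"] = self.policy.value
        out["amplicon_depth"] = self.amplicon_depth
        out["validation_alpha"] = self.validation_alpha
        out["validation_bonferroni"] = self.validation_bonferroni
        return out

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        sim_kwargs, screen_kwargs, top = {}, {}, {}
        sim_fields = {f.name for f in fields(SimulationConfig)}
        screen_fields = {f.name for f in fields(ScreenConfig)}
        for key, value in raw.items():
            name = key.split(".", 1)[-1]
            if key.startswith("screen.") or (
                    "." not in key and name in screen_fields):
                screen_kwargs[name] = value
            elif key.startswith("simulate.") or (
                    "." not in key and name in sim_fields):
                sim_kwargs[name] = value
            elif name == "policy":
                top["policy"] = OverlapPolicy(value)
            elif name in ("amplicon_depth", "validation_alpha",
                          "validation_bonferroni", "write_reads"):
                top[name] = value
            else:
                raise ValueError(f"unknown configuration key {key!r}")
        return cls(simulation=SimulationConfig(**sim_kwargs),
                   screen=ScreenConfig(**screen_kwargs),
                   user_set=frozenset(raw), **top)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    def log_parameters(self) -> None:
        for key, value in sorted(self.flat().items()):
            origin = "user" if key in self.user_set else "default"
            logger.info("param %s = %r (%s)", key, value, origin)


def run_pipeline(config: PipelineConfig, outdir, seed: int | None = None) -> Path:
    """Run the whole simulated experiment and write artifacts to ``outdir``.

    Stages: read simulation, coordinate dedup, pileup under the configured
    overlap policy, the discovery screen, amplicon validation of every
    accepted candidate (amplicon truth taken from the simulator's ground
    truth), and a cohort summary.  Returns the output directory.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        config = replace(config, simulation=replace(config.simulation, seed=seed),
                         user_set=config.user_set | {"simulate.seed"})
    config.log_parameters()
    (outdir / "params.yaml").write_text(
        yaml.safe_dump(config.flat(), sort_keys=True))

    logger.info("stage simulate")
    try:
        reads, truth, ref = simulate_patient_cohort(config.simulation)
    except Exception as exc:  # pragma: no cover - stage error propagation
        raise RuntimeError(f"stage simulate failed: {exc}") from exc
    manifest = cio.manifest_for_simulation(config.simulation)
    cio.write_truth_tsv(truth, outdir / "truth.tsv")
    manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    (outdir / "reference.txt").write_text(ref + "\n")
    if config.write_reads:
        cio.write_reads_tsv(reads, outdir / "reads.tsv")

    logger.info("stage count (policy=%s)", config.policy.value)
    reads = dedup_fragments(reads)
    pileups = build_pileup(reads, ref, config.policy)
    cio.write_pileup_tsv(pileups, outdir / "pileups.tsv")

    logger.info("stage screen")
    candidates = run_screen(pileups, manifest, config.screen)
    candidates.to_csv(outdir / "candidates.tsv", sep="\t", index=False,
                      float_format="%.6g")
    cio.write_vcf(candidates, outdir / "candidates.vcf",
                  region_length=config.simulation.target_region_length)

    logger.info("stage validate")
    accepted = candidates.loc[candidates["accepted"]]
    truth_key = {(r.sample_id, r.position, r.alt_base): r.true_af
                 for r in truth.itertuples()}
    amp_rng = np.random.default_rng(
        np.random.SeedSequence([config.simulation.seed, 1]))
    results = []
    for row in accepted.itertuples():
        true_af = truth_key.get((row.sample_id, row.position, row.alt_base), 0.0)
        patient, control = simulate_amplicon(
            row.ref_base, row.alt_base, true_af, config.amplicon_depth,
            config.simulation.error_rate, rng=amp_rng,
            position=row.position, sample_id=row.sample_id)
        results.append(validate_candidate(
            patient, control, row.alt_base,
            n_verifications=max(1, len(accepted)),
            alpha=config.validation_alpha,
            bonferroni=config.validation_bonferroni,
            strand_min_per_strand=config.screen.strand_min_per_strand,
            strand_bias_p=config.screen.strand_bias_p,
            population=row.population))
    results_table(results).to_csv(outdir / "validation.tsv", sep="\t",
                                  index=False, float_format="%.6g")

    logger.info("stage summarize")
    totals, by_group = validation_summary(results)
    lines = [f"{k}\t{v}" for k, v in sorted(totals.items())]
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")
    by_group.to_csv(outdir / "validation_by_group.tsv", sep="\t", index=False)
    logger.info("done: %d candidates, %d accepted, %d validated",
                len(candidates), len(accepted), totals["n_validated"])
    return outdir
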