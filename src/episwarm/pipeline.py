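"""End-to-end orchestration: detect -> annotate -> train -> evaluate.

A run is described by a :class:`RunConfig` (loadable from YAML).  One global
seed fans out to per-stage sub-seeds by hashing the stage name, so adding a
stage never perturbs the randomness of earlier ones.  Every run writes a
machine-readable manifest (config hash, resolved seeds, package version)
sufficient to reproduce it.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .enn import EmotionalNetwork
from .evaluation import kfold_evaluate
from .genotypes import read_genotypes, patterns_to_json
from .interaction_stats import records_to_frame
from .swarm import BPSOHS, SwarmConfig


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed: global seed mixed with the stage name."""
    return (int(global_seed) * 1000003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunConfig:
    genotypes: str
    out_dir: str = "episwarm_run"
    seed: int = 0
    swarm: dict = field(default_factory=dict)
    enn: dict = field(default_factory=dict)
    n_interactions: int = 5
    folds: int = 5
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            obj = yaml.safe_load(fh) or {}
        return cls(**obj)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def run_pipeline(config: RunConfig) -> dict:
    """Execute detect -> train -> evaluate and write all artifacts.

    Returns the run manifest (also written to ``manifest.json``).  Outputs:
    ``interactions.tsv`` (report table), ``interactions.json`` (interop
    form), ``model.json`` (fitted network), ``metrics.tsv`` (per-fold and
    mean confusion statistics).
    """
    geno_path = Path(config.genotypes)
    if not geno_path.exists():
        raise PipelineError(f"pre-flight: genotype file {geno_path} does not exist")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "version": __version__,
        "stages": {},
    }

    def _stage(name):
        seed = stage_seed(config.seed, name)
        manifest["stages"][name] = {"seed": seed}
        return seed

    data = read_genotypes(geno_path)

    # -- detect ----------------------------------------------------------
    try:
        seed = _stage("detect")
        cfg = SwarmConfig(**{**config.swarm, "seed": seed})
        results = BPSOHS(data, cfg).fit()
        records = results.records[: config.n_interactions]
        frame = records_to_frame(records, data.snp_ids)
        with open(out / "interactions.tsv", "w") as fh:
            fh.write(f"# episwarm {__version__} detect seed={seed} hash={config.config_hash()}\n")
            frame.to_csv(fh, sep="\t", index=False)
        interactions = [(r.pattern, r.odds_ratio) for r in records]
        (out / "interactions.json").write_text(patterns_to_json(interactions, data.snp_ids))
        manifest["stages"]["detect"]["n_archived"] = len(results.records)
    except Exception as exc:  # noqa: BLE001 - stage-named abort
        raise PipelineError(f"detect stage failed: {exc}") from exc

    # -- train -----------------------------------------------------------
    try:
        seed = _stage("train")
        fitted = EmotionalNetwork(data, interactions, seed=seed, **config.enn).fit()
        (out / "model.json").write_text(fitted.to_json(data.snp_ids))
        manifest["stages"]["train"]["final_training_accuracy"] = float(
            fitted.training_accuracy[-1]
        )
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"train stage failed: {exc}") from exc

    # -- evaluate --------------------------------------------------------
    try:
        seed = _stage("evaluate")
        report = kfold_evaluate(
            data,
            k=config.folds,
            seed=seed,
            swarm_config=SwarmConfig(**{**config.swarm, "seed": seed}),
            n_interactions=config.n_interactions,
            enn_params=dict(config.enn),
        )
        table = report.to_frame()
        means = report.mean()
        with open(out / "metrics.tsv", "w") as fh:
            fh.write(f"# episwarm {__version__} evaluate seed={seed} hash={config.config_hash()}\n")
            table.to_csv(fh, sep="\t")
            fh.write("# means (undefined folds excluded)\n")
            for name, (mu, sd, nu) in means.items():
                mu_s = "undefined" if mu is None else f"{mu:.6f}"
                fh.write(f"# {name}\t{mu_s}\t{'' if sd is None else f'{sd:.6f}'}\t{nu}\n")
        manifest["stages"]["evaluate"]["mean_accuracy"] = (
            None if means["accuracy"][0] is None else means["accuracy"][0]
        )
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"evaluate stage failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
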