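"""Pipeline orchestration: configuration, staged execution and run manifests.

A :class:`PipelineConfig` (YAML-serializable, schema-validated through
pydantic) fully determines a run: given the same inputs and seeds, every
output file is reproduced bit-for-bit. :func:`run_pipeline` executes

    simulate -> infer -> decompose -> components -> markers/REC

honoring per-stage toggles, and emits a :class:`RunManifest` recording the
config snapshot, input/output checksums, software version and per-stage
wall-clock times.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import io as nio
from . import __version__
from .datasets import ExpressionDataset
from .exceptions import InvalidArgumentError
from .interpretation import (
    binary_adjacency,
    differential_edge_score,
    mean_re_summary,
    rec,
    rec_pca,
    regulatory_effect,
    split_samples,
    top_k_markers,
)
from .kernel_net import KernelConfig, PenaltySpec, build_network_tensor
from .simulate import NoiseSpec, generate_dataset, random_profile_map
from .trip import component_scores, fit, fit_surrogate

log = logging.getLogger("netten")


class SimulateConfig(BaseModel):
    enabled: bool = True
    n: int = 60
    targets: int = 20
    regulators: int = 10
    sigma: float = 0.1
    mixture: tuple[float, float, float, float] = (0.6, 0.2, 0.1, 0.1)


class InferConfig(BaseModel):
    enabled: bool = True
    bandwidth: float | str = "auto"
    lam: float | str = "auto"
    alpha: float = 0.9
    recursion_steps: int = 2

    @field_validator("bandwidth", "lam")
    @classmethod
    def _auto_or_number(cls, v):
        if isinstance(v, str) and v != "auto":
            raise ValueError("must be a number or 'auto'")
        return v


class DecomposeConfig(BaseModel):
    enabled: bool = True
    j1: int = 5
    j2: int = 5
    gamma: float = 1.0
    head: str = "mlp"
    loss: str = "squared"
    max_iter: int = 200


class ComponentsConfig(BaseModel):
    enabled: bool = True
    mode: int = 2


class MarkersConfig(BaseModel):
    enabled: bool = True
    split: str = "median"
    N: int | None = None
    component: int = 1
    k: int = 10


class PipelineConfig(BaseModel):
    """Everything needed to reproduce a run bit-for-bit given the inputs."""

    seed: int = 0
    outdir: str = "netten_run"
    expression: str | None = None  # input TSV when simulate is disabled
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    infer: InferConfig = Field(default_factory=InferConfig)
    decompose: DecomposeConfig = Field(default_factory=DecomposeConfig)
    components: ComponentsConfig = Field(default_factory=ComponentsConfig)
    markers: MarkersConfig = Field(default_factory=MarkersConfig)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=True))


class RunManifest(BaseModel):
    config: dict
    version: str
    input_checksums: dict[str, str]
    output_checksums: dict[str, str]
    stage_seconds: dict[str, float]
    outputs: dict[str, str]
    complete: bool = False

    def write(self, path) -> None:
        Path(path).write_text(self.model_dump_json(indent=1))


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def auto_bandwidth(modulator: np.ndarray) -> float:
    """Silverman-style rule mapped to the exp{-d^2/b} parameterization.

    A Gaussian kernel of bandwidth h corresponds to b = 2 h^2; Silverman's
    rule h = 1.06 sigma n^(-1/5) gives a scale that tracks the modulator
    spread and sample count.
    """
    n = len(modulator)
    h = 1.06 * float(np.std(modulator)) * n ** (-1 / 5)
    return max(2.0 * h * h, 1e-6)


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise InvalidArgumentError(
            f"stage {stage!r} requires missing upstream file {path}"
        )
    return path


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the configured stages in order and write a run manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "dataset.tsv",
        "tensor": out / "tensor.h5",
        "model": out / "model.h5",
        "scores": out / "scores.tsv",
        "markers": out / "markers.tsv",
        "edges_high": out / "edges_high.tsv",
        "edges_low": out / "edges_low.tsv",
        "rec": out / "rec.tsv",
        "rec_pca": out / "rec_pca.tsv",
        "mean_re": out / "mean_re.tsv",
    }
    manifest = RunManifest(
        config=config.model_dump(),
        version=__version__,
        input_checksums={},
        output_checksums={},
        stage_seconds={},
        outputs={},
    )
    manifest_path = out / "manifest.json"

    def finish_stage(stage, t0, *produced):
        manifest.stage_seconds[stage] = round(time.perf_counter() - t0, 4)
        for key in produced:
            manifest.outputs[key] = str(paths[key])
            manifest.output_checksums[key] = _sha256(paths[key])
        manifest.write(manifest_path)

    try:
        # ---- simulate ----------------------------------------------------
        if config.simulate.enabled:
            t0 = time.perf_counter()
            log.info("simulate: n=%d targets=%d regulators=%d",
                     config.simulate.n, config.simulate.targets,
                     config.simulate.regulators)
            sim = config.simulate
            profiles = random_profile_map(sim.targets, sim.regulators,
                                          seed=config.seed, mixture=sim.mixture)
            truth = generate_dataset(
                sim.n, sim.regulators, sim.targets, profiles,
                noise=NoiseSpec(sigma=sim.sigma, seed=config.seed + 1),
                seed=config.seed,
            )
            data = truth.to_expression_dataset()
            nio.write_expression(data, paths["expression"])
            finish_stage("simulate", t0, "expression")
        elif config.expression is not None:
            data = nio.load_expression(config.expression)
            manifest.input_checksums["expression"] = _sha256(config.expression)
        else:
            data = None

        # ---- infer -------------------------------------------------------
        if config.infer.enabled:
            t0 = time.perf_counter()
            if data is None:
                data = nio.load_expression(_require(paths["expression"], "infer"))
            b = config.infer.bandwidth
            if b == "auto":
                b = auto_bandwidth(data.modulator)
            log.info("infer: bandwidth=%.4g lam=%s", b, config.infer.lam)
            tensor = build_network_tensor(
                data,
                kernel=KernelConfig(bandwidth=float(b)),
                penalty=PenaltySpec(lam=config.infer.lam, alpha=config.infer.alpha,
                                    recursion_steps=config.infer.recursion_steps),
            )
            nio.write_network_tensor(tensor, paths["tensor"])
            finish_stage("infer", t0, "tensor")

        # ---- decompose ---------------------------------------------------
        if config.decompose.enabled:
            t0 = time.perf_counter()
            tensor = nio.load_network_tensor(_require(paths["tensor"], "decompose"))
            tensors = tensor.slices()
            y = tensor.modulator
            if y is None:
                raise InvalidArgumentError("tensor carries no modulator to predict")
            log.info("decompose: J=(%d,%d) gamma=%.3g head=%s",
                     config.decompose.j1, config.decompose.j2,
                     config.decompose.gamma, config.decompose.head)
            model = fit(
                tensors, y,
                J=(config.decompose.j1, config.decompose.j2),
                gamma=config.decompose.gamma,
                loss_kind=config.decompose.loss,
                head=config.decompose.head,
                seed=config.seed,
                max_iter=config.decompose.max_iter,
            )
            nio.write_subspace_model(model, paths["model"])
            finish_stage("decompose", t0, "model")

        # ---- components --------------------------------------------------
        if config.components.enabled:
            t0 = time.perf_counter()
            model = nio.load_subspace_model(_require(paths["model"], "components"))
            tensor = nio.load_network_tensor(_require(paths["tensor"], "components"))
            tensors = tensor.slices()
            surrogate = fit_surrogate(model, tensors)
            scores = component_scores(tensors, model, surrogate,
                                      k=config.components.mode)
            nio.write_component_scores(scores, tensor.sample_ids, paths["scores"])
            log.info("components: mode=%d var_explained[0]=%.3f",
                     config.components.mode, scores.variance_explained[0])
            finish_stage("components", t0, "scores")

        # ---- markers / REC -----------------------------------------------
        if config.markers.enabled:
            t0 = time.perf_counter()
            tensor = nio.load_network_tensor(_require(paths["tensor"], "markers"))
            score_df = nio.load_component_scores(_require(paths["scores"], "markers"))
            if data is None:
                data = nio.load_expression(_require(paths["expression"], "markers"))
            col = f"pc_{config.markers.component}"
            pc = pd.Series(score_df[col].to_numpy(), index=score_df["sample"])
            split = split_samples(pc, mode=config.markers.split,
                                  N=config.markers.N,
                                  component=config.markers.component)
            A_high = binary_adjacency(tensor, split.high_ids, region=split)
            A_low = binary_adjacency(tensor, split.low_ids, region=split)
            dscore = differential_edge_score(A_high, A_low)
            k = min(config.markers.k, len(dscore))
            markers = top_k_markers(dscore, k=k)
            pd.DataFrame(
                {"gene": markers, "score": dscore.loc[markers].to_numpy()}
            ).to_csv(paths["markers"], sep="\t", index=False)

            for name, A in (("edges_high", A_high), ("edges_low", A_low)):
                m = A.matrix
                ls, js = np.nonzero(m.to_numpy())
                pd.DataFrame(
                    {
                        "regulator": m.columns[js],
                        "target": m.index[ls],
                        "region": name.split("_")[1],
                    }
                ).to_csv(paths[name], sep="\t", index=False)

            re_arr = regulatory_effect(tensor, data)
            rec_mat = pd.DataFrame(rec(re_arr), index=tensor.target_ids,
                                   columns=tensor.regulator_ids)
            rec_mat.rename_axis("target").to_csv(paths["rec"], sep="\t")

            marker_regs = [g for g in markers if g in rec_mat.columns]
            if len(marker_regs) >= 2:
                pcs = rec_pca(rec_mat, marker_regs)
                pcs["loadings"].rename_axis("gene").to_csv(paths["rec_pca"], sep="\t")
            else:
                pd.DataFrame(columns=["gene", "PC1", "PC2"]).to_csv(
                    paths["rec_pca"], sep="\t", index=False
                )
            mean_re_summary(re_arr, tensor, split.high_ids).to_csv(
                paths["mean_re"], sep="\t", index=False
            )
            finish_stage("markers", t0,
                         "markers", "edges_high", "edges_low", "rec",
                         "rec_pca", "mean_re")
    except Exception:
        manifest.complete = False
        manifest.write(manifest_path)
        raise

    manifest.complete = True
    manifest.write(manifest_path)
    return manifest
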