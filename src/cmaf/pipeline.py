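"""End-to-end pipeline wiring and the flat-file configuration layer.

``predict_all`` is the single code path every caller (CLI, cross-validation,
de-novo harness, acceptance checks) uses to turn a binary training network
and two input similarities into the four score matrices:

    WKNKN completion -> linear neighborhood similarities (drug & disease)
      -> LPRIA / NMFRIA / NCPRIA -> noisy-OR fusion (CMAF)

One global seed deterministically derives per-stage seeds by hashing the
stage name, so adding a stage never perturbs earlier stages' randomness.
"""

from __future__ import annotations

import dataclasses
import json
import time
import tomllib
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .core_data import (
    DrugDiseaseNetwork,
    ScoreMatrix,
    SimilarityMatrix,
    load_association_network,
    load_similarity_matrix,
    write_matrix,
)
from .ensemble import clip_unit, fuse_scores
from .errors import ValidationError
from .neighborhood import LnsParams, linear_neighborhood_similarity
from .predictors import (
    LpParams,
    NmfParams,
    lpria_predict,
    ncpria_predict,
    nmfria_fit,
    nmfria_predict,
)
from .wknkn import WknknParams, wknkn_complete

__all__ = [
    "PipelineParams",
    "PipelineConfig",
    "derive_seed",
    "predict_all",
    "run_pipeline",
]


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed: mix the global seed with a hash of the stage name."""
    return (int(global_seed) * 1000003 + zlib.crc32(stage.encode("utf-8"))) % (2**31)


@dataclass(frozen=True)
class PipelineParams:
    """Hyperparameters for every stage, at the method's published defaults."""

    wknkn: WknknParams = field(default_factory=WknknParams)
    lns_drug: LnsParams = field(default_factory=LnsParams)
    lns_disease: LnsParams = field(default_factory=LnsParams)
    lp: LpParams = field(default_factory=LpParams)
    nmf: NmfParams = field(default_factory=NmfParams)

    def validate(self) -> "PipelineParams":
        self.wknkn.validate()
        self.lns_drug.validate()
        self.lns_disease.validate()
        self.lp.validate()
        self.nmf.validate()
        return self

    @classmethod
    def with_seed(cls, seed: int, **overrides) -> "PipelineParams":
        """Defaults with the NMF seed derived from one global seed."""
        nmf = overrides.pop("nmf", NmfParams(seed=derive_seed(seed, "nmf")))
        return cls(nmf=nmf, **overrides)


def predict_all(
    net: DrugDiseaseNetwork,
    S_r: SimilarityMatrix,
    S_d: SimilarityMatrix,
    params: PipelineParams,
) -> dict[str, object]:
    """Run every stage on one training network; return all intermediates.

    Keys: ``completed`` (network), ``Sr_star``/``Sd_star`` (similarities),
    ``LPRIA``/``NMFRIA``/``NCPRIA``/``CMAF`` (score matrices).
    """
    params.validate()
    completed = wknkn_complete(net, S_r, S_d, params.wknkn)
    Sr_star = linear_neighborhood_similarity(
        completed.Y, params.lns_drug, ids=completed.drug_ids
    )
    Sd_star = linear_neighborhood_similarity(
        completed.Y.T, params.lns_disease, ids=completed.disease_ids
    )
    lp = lpria_predict(completed, Sr_star, Sd_star, params.lp)
    nmf = nmfria_predict(nmfria_fit(completed, Sr_star, Sd_star, params.nmf))
    ncp = ncpria_predict(completed, Sr_star, Sd_star)
    cmaf = fuse_scores(lp, clip_unit(nmf), ncp)
    return {
        "completed": completed,
        "Sr_star": Sr_star,
        "Sd_star": Sd_star,
        "LPRIA": lp,
        "NMFRIA": nmf,
        "NCPRIA": ncp,
        "CMAF": cmaf,
    }


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class PipelineConfig:
    """Flat key-value run configuration (TOML on disk)."""

    association: str
    drug_similarity: str
    disease_similarity: str
    output_dir: str = "cmaf_out"
    seed: int = 0
    wknkn_k: int = 5
    wknkn_decay: float = 0.5
    lns_k: int = 100
    lns_lambda: float = 1.0
    lp_alpha: float = 0.5
    nmf_rank: int = 100
    nmf_lambda_l: float = 2.0
    nmf_lambda_r: float = 1e-4
    nmf_lambda_d: float = 1e-4
    nmf_max_iter: int = 2000
    nmf_tol: float = 1e-6
    cv_folds: int = 10
    cv_repeats: int = 10

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - names
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        for required in ("association", "drug_similarity", "disease_similarity"):
            if required not in raw:
                raise ValidationError(f"config is missing required key {required!r}")
        cfg = cls(**raw)
        cfg.params()  # re-validate every stage's invariants up front
        return cfg

    def params(self) -> PipelineParams:
        return PipelineParams(
            wknkn=WknknParams(K=self.wknkn_k, T=self.wknkn_decay),
            lns_drug=LnsParams(K=self.lns_k, lam=self.lns_lambda),
            lns_disease=LnsParams(K=self.lns_k, lam=self.lns_lambda),
            lp=LpParams(alpha=self.lp_alpha),
            nmf=NmfParams(
                k=self.nmf_rank,
                lam_l=self.nmf_lambda_l,
                lam_r=self.nmf_lambda_r,
                lam_d=self.nmf_lambda_d,
                max_iter=self.nmf_max_iter,
                rel_tol=self.nmf_tol,
                seed=derive_seed(self.seed, "nmf"),
            ),
        ).validate()

    def load_inputs(self) -> tuple[DrugDiseaseNetwork, SimilarityMatrix, SimilarityMatrix]:
        net = load_association_network(self.association)
        S_r = load_similarity_matrix(self.drug_similarity, net.drug_ids)
        S_d = load_similarity_matrix(self.disease_similarity, net.disease_ids)
        return net, S_r, S_d


_OUTPUT_NAMES = {
    "completed": "completed.tsv",
    "Sr_star": "drug_lns.tsv",
    "Sd_star": "disease_lns.tsv",
    "LPRIA": "scores_lpria.tsv",
    "NMFRIA": "scores_nmfria.tsv",
    "NCPRIA": "scores_ncpria.tsv",
    "CMAF": "scores_cmaf.tsv",
}


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full pipeline from a config; write TSVs and a run manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    net, S_r, S_d = config.load_inputs()
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    results = predict_all(net, S_r, S_d, config.params())
    timings["pipeline_s"] = round(time.perf_counter() - t0, 3)
    for key, fname in _OUTPUT_NAMES.items():
        write_matrix(results[key], out / fname)
    manifest = {
        "cmaf_version": __version__,
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "timings": timings,
        "library_versions": {
            "numpy": np.__version__,
            "scipy": __import__("scipy").__version__,
            "pandas": __import__("pandas").__version__,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out
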