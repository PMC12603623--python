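"""Per-pathway Yeo-Johnson power transform with z-score standardization.

Each pathway's NES row is power transformed (lambda chosen by maximizing the
Yeo-Johnson profile log-likelihood) and standardized to mean 0, variance 1
across the dataset's samples.  The fitted (lambda, mean, sd) triples form a
frozen model that can be applied to new data without refitting - the frozen
path used when drug-treated samples are pushed through an untreated model.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .enrichment import EnrichmentMatrix

logger = logging.getLogger(__name__)

__all__ = ["PowerTransformModel", "fit_power_transform", "apply_power_transform"]

_LAMBDA_BOUNDS = (-5.0, 5.0)


@dataclass
class PowerTransformModel:
    """Frozen per-pathway Yeo-Johnson parameters: lambda, mean, sd."""

    params: pd.DataFrame  # index = pathway, columns = ["lambda", "mean", "sd"]
    tag: str = ""
    dropped: list[str] = field(default_factory=list)

    @property
    def pathway_names(self) -> list[str]:
        return list(self.params.index)

    def to_json(self, path) -> None:
        payload = {
            "tag": self.tag,
            "dropped": self.dropped,
            "pathways": {
                name: {
                    "lambda": float(row["lambda"]),
                    "mean": float(row["mean"]),
                    "sd": float(row["sd"]),
                }
                for name, row in self.params.iterrows()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "PowerTransformModel":
        with open(path) as fh:
            payload = json.load(fh)
        params = pd.DataFrame.from_dict(payload["pathways"], orient="index")
        params = params.rename(columns={"lambda": "lambda"})[["lambda", "mean", "sd"]]
        return cls(params=params, tag=payload.get("tag", ""), dropped=payload.get("dropped", []))


def _fit_lambda(x: np.ndarray) -> float:
    """Maximize the Yeo-Johnson profile log-likelihood over a bounded interval."""
    res = optimize.minimize_scalar(
        lambda lmb: -stats.yeojohnson_llf(lmb, x),
        bounds=_LAMBDA_BOUNDS,
        method="bounded",
        options={"xatol": 1e-6},
    )
    lam = float(res.x)
    if abs(lam - _LAMBDA_BOUNDS[0]) < 1e-3 or abs(lam - _LAMBDA_BOUNDS[1]) < 1e-3:
        logger.info("lambda estimate at search boundary: %.4f", lam)
    return lam


def fit_power_transform(
    m: EnrichmentMatrix, tag: str = ""
) -> tuple[PowerTransformModel, pd.DataFrame]:
    """Fit lambda per pathway, standardize, return (model, transformed matrix).

    Constant pathways (sd = 0 after transform) are dropped and logged; every
    retained output row has mean 0 and unit variance (ddof=0, matching the
    standardization convention of the usual power-transformer tooling).
    """
    rows = {}
    params = {}
    dropped = []
    for name, row in m.nes.iterrows():
        x = row.to_numpy(dtype=float)
        if len(x) < 3 or np.unique(x).size < 2:
            dropped.append(name)
            logger.info("dropping constant pathway %s in power transform", name)
            continue
        lam = _fit_lambda(x)
        t = stats.yeojohnson(x, lmbda=lam)
        mu, sd = float(t.mean()), float(t.std())
        if sd == 0.0 or not np.isfinite(sd):
            dropped.append(name)
            logger.info("dropping pathway %s: zero variance after transform", name)
            continue
        params[name] = {"lambda": lam, "mean": mu, "sd": sd}
        rows[name] = (t - mu) / sd
    if not rows:
        raise ValueError("all pathways dropped in power transform")
    model = PowerTransformModel(
        params=pd.DataFrame.from_dict(params, orient="index")[["lambda", "mean", "sd"]],
        tag=tag or m.species,
        dropped=dropped,
    )
    transformed = pd.DataFrame.from_dict(rows, orient="index", columns=m.nes.columns)
    return model, transformed


def apply_power_transform(model: PowerTransformModel, m: EnrichmentMatrix) -> pd.DataFrame:
    """Apply frozen (lambda, mean, sd) per pathway; never refits.

    Output rows of new data are generally *not* zero-mean/unit-variance -
    that is the point of the frozen contract.
    """
    missing = [p for p in m.pathway_names if p not in model.params.index]
    if missing:
        raise KeyError(f"pathways absent from power-transform model: {missing}")
    rows = {}
    for name in m.pathway_names:
        lam, mu, sd = model.params.loc[name, ["lambda", "mean", "sd"]]
        t = stats.yeojohnson(m.nes.loc[name].to_numpy(dtype=float), lmbda=float(lam))
        rows[name] = (t - mu) / sd
    return pd.DataFrame.from_dict(rows, orient="index", columns=m.nes.columns)
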