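"""Data ingestion, the bundled bladder-cancer fixture, run configuration,
result rendering and logging."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fit import LifetimeSample

__all__ = ["load_lifetimes", "bladder_cancer_remission_times", "report",
           "RunConfig", "setup_logging", "FIXTURES"]

log = logging.getLogger("gllsurv")

FIXTURES = ("bladder128",)


class DataFormatError(ValueError):
    """Malformed lifetime input (non-numeric, non-positive, or empty)."""


def setup_logging(verbosity: int = 0) -> None:
    level = logging.WARNING if verbosity <= 0 else logging.INFO if verbosity == 1 else logging.DEBUG
    logging.basicConfig(level=level, format="%(asctime)s %(name)s %(levelname)s %(message)s")


def bladder_cancer_remission_times() -> LifetimeSample:
    """The 128 bladder-cancer remission times (months) bundled as a fixture."""
    text = resources.files("gllsurv.data").joinpath("bladder128.txt").read_text()
    vals = [float(tok) for line in text.splitlines()
            if line.strip() and not line.startswith("#")
            for tok in line.replace(",", " ").split()]
    return LifetimeSample(np.array(vals))


def load_lifetimes(source) -> LifetimeSample:
    """Load a one-column sample of positive lifetimes.

    `source` is either the fixture name "bladder128" or a path to a
    whitespace/comma-separated plain-text file.  Non-numeric tokens and
    non-positive values raise DataFormatError with the offending line.
    """
    if str(source) in FIXTURES:
        return bladder_cancer_remission_times()
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(f"no such file or fixture: {source}")
    values = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.split("#")[0].strip()
        if not line:
            continue
        for tok in line.replace(",", " ").split():
            try:
                v = float(tok)
            except ValueError:
                raise DataFormatError(f"line {lineno}: non-numeric token {tok!r}") from None
            if v <= 0:
                raise DataFormatError(f"line {lineno}: non-positive lifetime {v}")
            values.append(v)
    if not values:
        raise DataFormatError(f"{path}: no data found")
    log.info("loaded %d lifetimes from %s", len(values), path)
    return LifetimeSample(np.array(values))


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.reset_index().to_dict(orient="records"))
    return obj


def report(results, format: str = "text") -> str:
    """Render results losslessly as JSON, or as human-readable text/TSV."""
    if format == "json":
        return json.dumps(_jsonable(results), indent=2)
    if format == "tsv":
        if isinstance(results, pd.DataFrame):
            return results.to_csv(sep="\t")
        return pd.DataFrame(_jsonable(results)).to_csv(sep="\t", index=False)
    if format == "text":
        if isinstance(results, pd.DataFrame):
            return results.to_string()
        return yaml.safe_dump(_jsonable(results), sort_keys=False, default_flow_style=False)
    raise ValueError(f"unknown format {format!r}; use text, json or tsv")


@dataclass
class RunConfig:
    """Plumbing for a fully-reproducible run; every field maps to a CLI flag."""

    data: str = "bladder128"
    models: tuple = ("GLL", "W2", "LL2", "BurrXII", "ExpW", "LL3", "LN3", "W3", "G3")
    seed: int = 0
    level: float = 0.95
    starts: int = 10
    # simulation
    scenario: str = "I"
    sizes: tuple = (50, 100, 300, 600, 900, 1200, 1500)
    replicates: int = 1500
    # bayes
    prior: tuple = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    chains: int = 3
    iters: int = 50_000
    burnin: int = 5_000
    thin: int = 5
    # output
    format: str = "text"
    out: str | None = None
    verbosity: int = 0
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        cfg = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        kwargs = {k: v for k, v in cfg.items() if k in known}
        extra = {k: v for k, v in cfg.items() if k not in known}
        rc = cls(**kwargs)
        rc.extra = extra
        for key in ("models", "sizes", "prior"):
            v = getattr(rc, key)
            if isinstance(v, list):
                setattr(rc, key, tuple(v))
        return rc
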