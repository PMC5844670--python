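"""Run configuration and report writing.

A run configuration is one structured-text document (YAML mapping; JSON is
a subset of YAML and is accepted unchanged) with up to four sections —
``design``, ``pool``, ``sim``, plus ``output_dir`` / ``formats`` — whose
fields mirror the dataclasses they populate.  Unknown keys are rejected.
An empty document yields the default scenario of the motivating trial
(cohort 4,377; 1,306 eligible; 504 offered; consent 207/504; attrition
0.25; rho 0.5; effect 0.25).

Every report written to disk embeds the seed, the tool version, and a hash
of the full configuration, so any artifact can be regenerated from its own
header.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from .cohort import SimConfig
from .params import DesignParams, PoolSpec

__all__ = ["RunConfig", "ConfigParseError", "parse_config", "write_report"]

VERSION = "0.1.0"


class ConfigParseError(ValueError):
    """The configuration document is malformed or holds unknown keys."""


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of one reproducible run."""

    design: DesignParams = field(default_factory=DesignParams)
    pool: PoolSpec = field(default_factory=PoolSpec)
    sim: SimConfig = field(default_factory=SimConfig)
    output_dir: str = "."
    formats: tuple[str, ...] = ("text",)

    def __post_init__(self) -> None:
        bad = set(self.formats) - {"csv", "json", "text"}
        if bad:
            raise ConfigParseError(f"unknown report formats: {sorted(bad)}")

    def to_dict(self) -> dict[str, Any]:
        return {
            "design": dataclasses.asdict(self.design),
            "pool": dataclasses.asdict(self.pool),
            "sim": dataclasses.asdict(self.sim),
            "output_dir": self.output_dir,
            "formats": sorted(self.formats),
        }

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @property
    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _build(cls, section: str, values: Mapping[str, Any]):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(values) - known
    if unknown:
        raise ConfigParseError(
            f"unknown key(s) in '{section}': {sorted(unknown)}")
    return cls(**values)


def parse_config(source: str | Path | Mapping[str, Any] | None) -> RunConfig:
    """Parse a YAML/JSON document (text, path, or mapping) into a RunConfig.

    Unknown keys raise :class:`ConfigParseError`; out-of-range values raise
    the originating dataclass's validation error, which names the field.
    """
    if source is None:
        data: Mapping[str, Any] = {}
    elif isinstance(source, Mapping):
        data = source
    else:
        text = Path(source).read_text() if isinstance(source, Path) else source
        try:
            data = yaml.safe_load(text) or {}
        except yaml.YAMLError as exc:
            raise ConfigParseError(f"malformed config document: {exc}") from exc
        if not isinstance(data, Mapping):
            raise ConfigParseError(
                f"config document must be a mapping, got {type(data).__name__}")

    known_sections = {"design", "pool", "sim", "output_dir", "formats"}
    unknown = set(data) - known_sections
    if unknown:
        raise ConfigParseError(f"unknown top-level key(s): {sorted(unknown)}")

    kwargs: dict[str, Any] = {}
    if "design" in data:
        kwargs["design"] = _build(DesignParams, "design", data["design"])
    if "pool" in data:
        kwargs["pool"] = _build(PoolSpec, "pool", data["pool"])
    if "sim" in data:
        kwargs["sim"] = _build(SimConfig, "sim", data["sim"])
    if "output_dir" in data:
        kwargs["output_dir"] = str(data["output_dir"])
    if "formats" in data:
        kwargs["formats"] = tuple(data["formats"])
    return RunConfig(**kwargs)


def _as_frame(results: Any) -> pd.DataFrame:
    if isinstance(results, pd.DataFrame):
        return results
    if dataclasses.is_dataclass(results) and not isinstance(results, type):
        return pd.DataFrame([dataclasses.asdict(results)])
    if isinstance(results, Mapping):
        return pd.DataFrame([dict(results)])
    raise TypeError(f"cannot serialize results of type {type(results).__name__}")


def write_report(results: Any, path: str | Path, fmt: str = "csv",
                 config: RunConfig | None = None,
                 seed: int | None = None) -> Path:
    """Write a results table with an embedded provenance header.

    CSV reports carry ``# key: value`` comment lines before the header row;
    JSON reports mirror the same rows under ``"results"`` with the metadata
    under ``"meta"``; text reports are aligned, human-readable tables.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = _as_frame(results)
    meta = {
        "tool": "cmrct",
        "version": VERSION,
        "seed": seed,
        "config_hash": config.config_hash if config is not None else None,
    }
    if fmt == "csv":
        header = "".join(f"# {k}: {v}\n" for k, v in meta.items())
        path.write_text(header + df.to_csv(index=False))
    elif fmt == "json":
        payload = {"meta": meta, "results": df.to_dict(orient="records")}
        path.write_text(json.dumps(payload, indent=2, default=str) + "\n")
    elif fmt == "text":
        header = "".join(f"{k}: {v}\n" for k, v in meta.items())
        path.write_text(header + "\n" + df.to_string(index=False) + "\n")
    else:
        raise ConfigParseError(f"unknown report format {fmt!r}")
    return path


def read_report_csv(path: str | Path) -> pd.DataFrame:
    """Read back a CSV report, skipping the provenance header."""
    return pd.read_csv(path, comment="#")
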