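"""CSV readers/writers and run configuration.

Datasets are plain CSV, one row per sample: ``sample_id, risk_factor,
rep1..repN`` with censored cells left empty (``<10``-style tokens from
instrument exports are also accepted on read).  Assay constants (LOQ,
extraction efficiency, volumes, seed) travel in a YAML sidecar next to
the CSV so the spreadsheet-safe data file stays self-contained.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .simulate import CensoredDataset, SampleRecord, ScenarioConfig

__all__ = [
    "SchemaError",
    "RunConfig",
    "sidecar_path",
    "read_dataset",
    "write_dataset",
    "load_config",
]

logger = logging.getLogger(__name__)

# generative placeholders when a sidecar carries only assay constants
_ASSAY_ONLY_DEFAULTS = {"beta0": 0.0, "beta1": 0.0, "sigma": 1.0}


class SchemaError(ValueError):
    """Raised when an input file violates the dataset schema."""


@dataclass
class RunConfig:
    """Bundle of scenario, prior, sampler and path settings for a run."""

    scenario: dict = field(default_factory=dict)
    priors: dict = field(default_factory=dict)
    mcmc: dict = field(default_factory=dict)
    methods: list[str] = field(default_factory=list)
    paths: dict = field(default_factory=dict)
    log_level: str = "INFO"


def sidecar_path(path: str | Path) -> Path:
    path = Path(path)
    return path.with_suffix(path.suffix + ".meta.yaml")


def _config_fields() -> set[str]:
    return {f.name for f in dataclasses.fields(ScenarioConfig)}


def write_dataset(dataset: CensoredDataset, path: str | Path) -> None:
    """Write a dataset as CSV plus a YAML sidecar of assay constants.

    Censored cells are serialised as empty strings; the simulated truth
    column is included when present so simulated datasets round-trip
    exactly.
    """
    path = Path(path)
    cfg = dataset.config
    rows = []
    has_truth = all(r.true_log10_quantity is not None for r in dataset.records)
    for rec in dataset.records:
        row: dict = {"sample_id": rec.sample_id, "risk_factor": rec.risk_indicator}
        for i, (value, flagged) in enumerate(
            zip(rec.replicate_counts, rec.censored_flags), start=1
        ):
            row[f"rep{i}"] = "" if flagged else value
        if has_truth:
            row["true_log10"] = rec.true_log10_quantity
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    meta = dataclasses.asdict(cfg)
    with open(sidecar_path(path), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)


def _parse_cell(raw, row_label: str, loq: int):
    """Return (value, censored) for one replicate cell."""
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return None, True
    text = str(raw).strip()
    if text == "" or text.upper() in ("NA", "ND"):
        return None, True
    if text.startswith("<"):
        return None, True
    try:
        value = float(text)
    except ValueError as exc:
        raise SchemaError(f"{row_label}: unparseable replicate value {raw!r}") from exc
    if value < 0:
        raise SchemaError(f"{row_label}: negative replicate count {value}")
    if value != int(value):
        raise SchemaError(f"{row_label}: replicate count {value} is not an integer")
    if value < loq:
        raise SchemaError(
            f"{row_label}: uncensored value {int(value)} is below the LOQ ({loq}); "
            "censored cells must be empty or '<LOQ'"
        )
    return int(value), False


def read_dataset(path: str | Path) -> CensoredDataset:
    """Read a dataset CSV (and its sidecar) into a CensoredDataset.

    Empty cells, ``NA``/``ND`` and ``<``-prefixed tokens are treated as
    censored.  Out-of-contract values (missing columns, negative
    counts, numeric values below the LOQ) raise :class:`SchemaError`
    naming the offending row.
    """
    path = Path(path)
    side = sidecar_path(path)
    if not side.exists():
        raise SchemaError(f"missing sidecar metadata file: {side}")
    with open(side) as fh:
        meta = yaml.safe_load(fh) or {}
    known = _config_fields()
    cfg_kwargs = {k: v for k, v in meta.items() if k in known}
    for key, default in _ASSAY_ONLY_DEFAULTS.items():
        cfg_kwargs.setdefault(key, default)

    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"sample_id", "risk_factor"}
    if not required.issubset(df.columns):
        raise SchemaError(f"missing required columns: {sorted(required - set(df.columns))}")
    rep_cols = sorted(
        (c for c in df.columns if c.startswith("rep") and c[3:].isdigit()),
        key=lambda c: int(c[3:]),
    )
    if not rep_cols:
        raise SchemaError("no replicate columns (rep1, rep2, ...) found")
    cfg_kwargs["n_samples"] = len(df)
    cfg_kwargs["n_replicates"] = len(rep_cols)
    config = ScenarioConfig(**cfg_kwargs)

    records = []
    for idx, row in df.iterrows():
        label = f"row {idx + 1} (sample_id={row['sample_id']})"
        risk = row["risk_factor"].strip()
        if risk not in ("0", "1"):
            raise SchemaError(f"{label}: risk_factor must be 0 or 1, got {risk!r}")
        values, flags = [], []
        for col in rep_cols:
            value, censored = _parse_cell(row[col], label, config.loq)
            values.append(value)
            flags.append(censored)
        truth = None
        if "true_log10" in df.columns and row["true_log10"].strip():
            truth = float(row["true_log10"])
        records.append(
            SampleRecord(
                sample_id=row["sample_id"],
                risk_indicator=int(risk),
                replicate_counts=tuple(values),
                censored_flags=tuple(flags),
                true_log10_quantity=truth,
            )
        )
    dataset = CensoredDataset(records=records, config=config)
    logger.info(
        "loaded %d samples x %d replicates = %d observations from %s",
        dataset.n_samples,
        config.n_replicates,
        dataset.n_observations,
        path,
    )
    return dataset


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration with module sections."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise SchemaError(f"config root must be a mapping, got {type(raw).__name__}")
    allowed = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - allowed
    if unknown:
        raise SchemaError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)
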