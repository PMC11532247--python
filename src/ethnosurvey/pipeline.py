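"""End-to-end report assembly: one config in, a reproducible bundle out.

A :class:`RunConfig` names the inputs (or asks for synthetic ones), the
analysis policies (NC override, RI convention, rounding, VIF threshold)
and a seed.  :func:`run_pipeline` executes whichever stages have inputs,
writes CSV outputs plus a JSON manifest recording versions, the seed and
a hash of the resolved configuration, and is byte-reproducible for a
fixed (config, seed, inputs) triple.

When no use-report file is given, the pipeline degrades to the packaged
reference citation dataset: the index table is then limited to FC and
RFC (the only columns recomputable from citation counts alone), with a
logged notice.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .capabilities import compare_groups, read_perception_statements
from .exceptions import EthnosurveyError
from .indices import RoundingPolicy, compute_index_table, index_table_to_frame
from .preference import fit_logit, read_preference_records, records_to_frame, vif_screen
from .use_reports import load_reference_citations, read_use_reports

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of one pipeline run."""

    output_dir: str
    reports_path: str | None = None
    statements_path: str | None = None
    preferences_path: str | None = None
    nc_override: int | None = None
    ri_convention: str = "raw_rfc"
    rounding_mode: str = "truncate"
    rounding_places: int = 3
    vif_threshold: float = 5.0
    outcome_column: str = "prefers_herbal"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path, encoding="utf-8") as handle:
            raw = yaml.safe_load(handle) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


def _categories_override(nc: int) -> list[str]:
    return [f"category-{i + 1}" for i in range(nc)]


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage with an input; returns the manifest dictionary."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    notices: list[str] = []
    rounding = RoundingPolicy(config.rounding_mode, config.rounding_places)

    # --- indices stage -----------------------------------------------------
    if config.reports_path is not None:
        path = Path(config.reports_path)
        if not path.exists():
            raise EthnosurveyError(f"[indices] input path does not exist: {path}")
        use_categories = (
            _categories_override(config.nc_override) if config.nc_override else None
        )
        survey = read_use_reports(path, use_categories=use_categories)
        rows = compute_index_table(survey, convention=config.ri_convention)
        frame = index_table_to_frame(rows, rounding)
        target = out_dir / "index_table.csv"
        frame.to_csv(target, index=False)
        outputs["index_table"] = target.name
    else:
        reference = load_reference_citations()
        notice = (
            "no use-report input: index table limited to FC and RFC from the "
            "packaged reference citations"
        )
        logger.info(notice)
        notices.append(notice)
        frame = pd.DataFrame(
            {
                "species": [r.species_name for r in reference],
                "fc": [r.fc for r in reference],
                "rfc": [r.fc / reference.n_informants for r in reference],
            }
        )
        frame["rfc_fmt"] = frame["rfc"].map(rounding.apply)
        target = out_dir / "index_table.csv"
        frame.to_csv(target, index=False)
        outputs["index_table"] = target.name

    # --- capability stage --------------------------------------------------
    if config.statements_path is not None:
        path = Path(config.statements_path)
        if not path.exists():
            raise EthnosurveyError(f"[capabilities] input path does not exist: {path}")
        statements = read_perception_statements(path)
        matrix = compare_groups(statements)
        cells = []
        for (group, medicine), tally in sorted(matrix.items()):
            cell = tally.to_frame()
            cell.insert(0, "user_group", group)
            cell.insert(1, "medicine", medicine)
            cells.append(cell)
        target = out_dir / "capability_tallies.csv"
        pd.concat(cells, ignore_index=True).to_csv(target, index=False)
        outputs["capability_tallies"] = target.name
    else:
        notices.append("no perception-statement input: capability stage skipped")
        logger.info(notices[-1])

    # --- preference stage --------------------------------------------------
    if config.preferences_path is not None:
        path = Path(config.preferences_path)
        if not path.exists():
            raise EthnosurveyError(f"[logit] input path does not exist: {path}")
        records = read_preference_records(path, outcome=config.outcome_column)
        x, _ = records_to_frame(records)
        kept, excluded = vif_screen(x, threshold=config.vif_threshold)
        fit = fit_logit(records, covariates=kept)
        fit.excluded = excluded
        summary = fit.summary_frame()
        target = out_dir / "logit_table.csv"
        summary.to_csv(target, index=False)
        outputs["logit_table"] = target.name
        meta = {
            "converged": fit.converged,
            "iterations": fit.n_iter,
            "log_likelihood": fit.llf,
            "excluded_covariates": excluded,
        }
        meta_target = out_dir / "logit_meta.json"
        meta_target.write_text(json.dumps(meta, sort_keys=True, indent=2))
        outputs["logit_meta"] = meta_target.name
    else:
        notices.append("no preference input: logit stage skipped")
        logger.info(notices[-1])

    manifest = {
        "package": "ethnosurvey",
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "outputs": outputs,
        "notices": notices,
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, sort_keys=True, indent=2))
    resolved = out_dir / "resolved_config.yaml"
    resolved.write_text(yaml.safe_dump(asdict(config), sort_keys=True))
    return manifest
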