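"""End-to-end orchestration: DE calls -> URA scoring -> curation -> prioritization.

Also hosts the robustness filter applied to published regulator summaries
(|activation z| > 2, overlap p < 0.05, at least five network genes) and the
flat ``key=value`` configuration format used by the command line.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .dge import call_degs, read_matrix, write_deg_table
from .kb import RegulatorKB, read_kb
from .ura import run_ura, write_ura_table
from .curate import curate_all, prioritize_degs, networks_to_frame

logger = logging.getLogger("uranet")


@dataclass
class PipelineConfig:
    matrix: str = ""
    kb: str = ""
    out_dir: str = "uranet_out"
    alpha_deg: float = 0.05
    cpm_threshold: float = 1.0
    z_state_threshold: float = 2.0
    min_consistent_targets: int = 5
    p_overlap_threshold: float = 0.05
    bh_scope: str = "per_drug"
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.alpha_deg < 1:
            raise ValueError("alpha_deg must be in (0, 1)")
        if self.cpm_threshold < 0:
            raise ValueError("cpm_threshold must be >= 0")
        for name in ("z_state_threshold", "p_overlap_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_consistent_targets < 1:
            raise ValueError("min_consistent_targets must be >= 1")
        if self.bh_scope not in ("per_drug", "global"):
            raise ValueError(f"unknown bh_scope: {self.bh_scope!r}")


_FIELD_TYPES = {f.name: f.type for f in dataclasses.fields(PipelineConfig)}


def read_config(path, **overrides) -> PipelineConfig:
    """Parse a flat ``key=value`` config file; keyword overrides win."""
    values = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value")
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if key not in _FIELD_TYPES:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
            values[key] = raw
    for key, raw in values.items():
        ftype = _FIELD_TYPES[key]
        if ftype in ("int", int):
            values[key] = int(raw)
        elif ftype in ("float", float):
            values[key] = float(raw)
    values.update({k: v for k, v in overrides.items() if v is not None})
    return PipelineConfig(**values)


def _setup_run_logging(out_dir: Path) -> logging.Handler:
    handler = logging.FileHandler(out_dir / "run.log", mode="a")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    if not any(isinstance(h, logging.StreamHandler)
               and not isinstance(h, logging.FileHandler)
               for h in logger.handlers):
        stream = logging.StreamHandler(sys.stderr)
        stream.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        logger.addHandler(stream)
    logger.setLevel(logging.INFO)
    return handler


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run all stages, writing degs/ura/networks/prioritized TSVs plus a run log.

    Deterministic: rerunning with the same inputs and config rewrites identical
    tables. An empty knowledge base is not an error — the DEG table is still
    produced and the downstream tables are written empty with a warning.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = _setup_run_logging(out_dir)
    try:
        logger.info("uranet %s starting; config=%s", __version__,
                    dataclasses.asdict(config))
        try:
            matrix = read_matrix(config.matrix)
        except Exception as exc:
            raise RuntimeError(f"stage read_matrix failed: {exc}") from exc
        try:
            kb = read_kb(config.kb)
        except Exception as exc:
            raise RuntimeError(f"stage read_kb failed: {exc}") from exc
        logger.info("inputs: %d genes x %d conditions, %d KB edges",
                    matrix.shape[0], matrix.shape[1], len(kb))

        paths = {name: out_dir / f"{name}.tsv"
                 for name in ("degs", "ura", "networks", "prioritized")}
        try:
            degs = call_degs(matrix, config.alpha_deg,
                             cpm_threshold=config.cpm_threshold,
                             bh_scope=config.bh_scope)
        except Exception as exc:
            raise RuntimeError(f"stage dge failed: {exc}") from exc
        write_deg_table(degs, paths["degs"])
        logger.info("dge: %d rows, %d DEG calls", len(degs),
                    int(degs["is_deg"].sum()))

        if len(kb) == 0:
            logger.warning("empty knowledge base: URA, curation and "
                           "prioritization outputs will be empty")
            ura = run_ura_empty()
            nets = []
        else:
            try:
                ura = run_ura(degs, kb, config.alpha_deg,
                              z_state_threshold=config.z_state_threshold)
                nets = curate_all(
                    ura, degs, kb, alpha=config.alpha_deg,
                    min_consistent_targets=config.min_consistent_targets,
                    z_state_threshold=config.z_state_threshold,
                    p_overlap_threshold=config.p_overlap_threshold)
            except Exception as exc:
                raise RuntimeError(f"stage ura/curation failed: {exc}") from exc
        write_ura_table(ura, paths["ura"])
        networks_to_frame(nets).to_csv(paths["networks"], sep="\t", index=False)
        logger.info("ura: %d scored pairs; %d robust networks", len(ura),
                    sum(net.robust for net in nets))

        try:
            prioritized = prioritize_degs(degs, nets)
        except Exception as exc:
            raise RuntimeError(f"stage prioritize failed: {exc}") from exc
        prioritized.to_csv(paths["prioritized"], sep="\t", index=False)
        logger.info("prioritized: %d DEGs (%d network tier)", len(prioritized),
                    int((prioritized["priority_tier"] == "network").sum()))
        return paths
    finally:
        logger.removeHandler(handler)
        handler.close()


def run_ura_empty() -> pd.DataFrame:
    from .ura import URA_COLUMNS
    return pd.DataFrame(columns=URA_COLUMNS)


def robustness_filter(rows: pd.DataFrame, *, z_threshold: float = 2.0,
                      p_threshold: float = 0.05, min_genes: int = 5
                      ) -> tuple[int, pd.DataFrame]:
    """Apply the robust-network screen to a regulator summary table.

    Keeps rows with |activation_z| > z_threshold AND p_overlap < p_threshold
    AND n_genes >= min_genes; returns (count, surviving subset).
    """
    required = {"activation_z", "p_overlap", "n_genes"}
    missing = required - set(rows.columns)
    if missing:
        raise ValueError(f"summary table missing columns: {sorted(missing)}")
    z = pd.to_numeric(rows["activation_z"])
    p = pd.to_numeric(rows["p_overlap"])
    n = pd.to_numeric(rows["n_genes"], downcast="integer")
    keep = (z.abs() > z_threshold) & (p < p_threshold) & (n >= min_genes)
    surviving = rows[keep]
    return int(keep.sum()), surviving
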