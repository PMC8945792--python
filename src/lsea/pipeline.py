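"""Reproducible end-to-end runs: ingest -> filter -> normalize -> VST ->
differential abundance -> ranking -> enrichment -> correlation.

A run is fully described by a :class:`RunConfig` (YAML-serializable);
executing it writes every intermediate table as TSV, a JSON manifest
(config hash, seed, versions, input checksums, per-stage row counts) and
a plain-text log into the output directory. Re-running the same config
reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .correlate import ProteinPanel, correlate_matrix
from .diffab import RANK_METRICS, normalize, rank_metric, size_factors, vst, wald_test
from .enrichment import run_lsea
from .io import _read_table, majority_presence_filter, read_matrix
from .registry import LipidRegistry
from .sets import read_gmt

STAGES = (
    "ingest",
    "filter",
    "normalize",
    "vst",
    "diffab",
    "enrich",
    "correlate",
)


@dataclass
class RunConfig:
    values: str
    meta: str
    registry: str | None = None
    gmt: str | None = None
    proteins: str | None = None
    outdir: str = "lsea_run"
    # contrast: metadata factor and its two levels (B over A)
    factor: str = "treatment"
    level_b: str = "DEP"
    level_a: str = "CTRL"
    stratum: dict[str, str] = field(default_factory=dict)
    # thresholds
    min_presence: float = 0.5
    q_cut: float = 0.05
    min_set_size: int = 3
    max_set_size: int = 500
    # enrichment
    rank_by: str = "wald_z"
    p_exp: float = 1.0
    n_perm: int = 1000
    seed: int = 0
    # correlation
    alpha_norm: float = 0.05
    vst_pseudocount: float = 1.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def validate(cfg: RunConfig) -> list[str]:
    """All validation problems at once; empty list means runnable."""
    errors: list[str] = []
    for name in ("values", "meta"):
        path = getattr(cfg, name)
        if not path or not Path(path).exists():
            errors.append(f"{name} file not found: {path!r}")
    for name in ("registry", "gmt", "proteins"):
        path = getattr(cfg, name)
        if path is not None and not Path(path).exists():
            errors.append(f"{name} file not found: {path!r}")
    if not 0 <= cfg.min_presence < 1:
        errors.append(f"min_presence must be in [0, 1), got {cfg.min_presence}")
    if not 0 < cfg.q_cut <= 1:
        errors.append(f"q_cut must be in (0, 1], got {cfg.q_cut}")
    if cfg.n_perm < 100:
        errors.append(f"n_perm must be >= 100, got {cfg.n_perm}")
    if cfg.p_exp < 0:
        errors.append(f"p_exp must be >= 0, got {cfg.p_exp}")
    if not 1 <= cfg.min_set_size <= cfg.max_set_size:
        errors.append("need 1 <= min_set_size <= max_set_size")
    if cfg.rank_by not in RANK_METRICS:
        errors.append(f"rank_by must be one of {RANK_METRICS}")
    if not 0 < cfg.alpha_norm < 1:
        errors.append(f"alpha_norm must be in (0, 1), got {cfg.alpha_norm}")
    if cfg.vst_pseudocount <= 0:
        errors.append("vst_pseudocount must be positive")
    if not errors and Path(cfg.meta).exists():
        meta = _read_table(cfg.meta)
        if cfg.factor not in meta.columns:
            errors.append(f"contrast factor {cfg.factor!r} not in metadata")
        else:
            sub = meta
            for col, val in cfg.stratum.items():
                if col not in meta.columns:
                    errors.append(f"stratum column {col!r} not in metadata")
                    break
                sub = sub[sub[col].astype(str) == str(val)]
            else:
                counts = sub[cfg.factor].astype(str).value_counts()
                for lev in (cfg.level_a, cfg.level_b):
                    if counts.get(lev, 0) < 2:
                        errors.append(
                            f"contrast level {lev!r} has "
                            f"{counts.get(lev, 0)} samples in stratum; need >= 2"
                        )
    return errors


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run(cfg: RunConfig) -> Path:
    """Execute all stages; returns the run directory."""
    errors = validate(cfg)
    if errors:
        raise ValueError("invalid run config:\n" + "\n".join(errors))
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = logging.getLogger("lsea.run")
    log.setLevel(logging.INFO)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    manifest: dict = {
        "package": "lsea",
        "version": __version__,
        "config": cfg.to_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(cfg.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "seed": cfg.seed,
        "inputs": {
            name: {"path": str(getattr(cfg, name)),
                   "sha256": _sha256(getattr(cfg, name))}
            for name in ("values", "meta", "registry", "gmt", "proteins")
            if getattr(cfg, name)
        },
        "stages": {},
    }
    stage_files: dict[str, str] = {}

    def record(stage: str, fname: str, n_rows: int, note: str) -> None:
        stage_files[stage] = fname
        manifest["stages"][stage] = {"output": fname, "n_rows": int(n_rows)}
        log.info("%s: %s", stage, note)

    try:
        registry = (
            LipidRegistry.from_tsv(cfg.registry) if cfg.registry else None
        )
        matrix = read_matrix(cfg.values, cfg.meta, registry)
        matrix.values.to_csv(outdir / "01_matrix.tsv", sep="\t")
        record("ingest", "01_matrix.tsv", matrix.n_lipids,
               f"{matrix.n_lipids} lipids x {matrix.n_samples} samples "
               f"({len(matrix.unresolved)} unresolved names)")

        filtered, report = majority_presence_filter(matrix, cfg.min_presence)
        filtered.values.to_csv(outdir / "02_filtered.tsv", sep="\t")
        report.to_csv(outdir / "02_presence_report.tsv", sep="\t")
        record("filter", "02_filtered.tsv", filtered.n_lipids,
               f"presence filter: {matrix.n_lipids} -> {filtered.n_lipids} lipids")

        stratum_matrix = (
            filtered.select(**cfg.stratum) if cfg.stratum else filtered
        )
        s = size_factors(stratum_matrix)
        normed = normalize(stratum_matrix.values, s)
        s.to_csv(outdir / "03_size_factors.tsv", sep="\t")
        normed.to_csv(outdir / "03_normalized.tsv", sep="\t")
        record("normalize", "03_normalized.tsv", normed.shape[0],
               f"median-of-ratios over {normed.shape[1]} samples")

        vst_mat = vst(normed, cfg.vst_pseudocount)
        vst_mat.to_csv(outdir / "04_vst.tsv", sep="\t")
        record("vst", "04_vst.tsv", vst_mat.shape[0],
               f"log2(x + {cfg.vst_pseudocount}) transform")

        groups = stratum_matrix.meta[cfg.factor].astype(str)
        res = wald_test(
            stratum_matrix.values, groups,
            level_a=cfg.level_a, level_b=cfg.level_b,
        )
        res.to_csv(outdir / "05_diffab.tsv", sep="\t")
        n_sig = int((res["q"] < cfg.q_cut).sum())
        record("diffab", "05_diffab.tsv", len(res),
               f"{cfg.level_b} vs {cfg.level_a}: {n_sig} lipids at "
               f"q < {cfg.q_cut}")

        ranks = rank_metric(res, cfg.rank_by)
        ranks.to_csv(outdir / "06_ranks.tsv", sep="\t", index=False)

        if cfg.gmt:
            coll = read_gmt(cfg.gmt, registry)
            enr, curves, skipped = run_lsea(
                ranks, coll,
                p_exp=cfg.p_exp, n_perm=cfg.n_perm,
                min_size=cfg.min_set_size, max_size=cfg.max_set_size,
                seed=cfg.seed,
            )
            out = enr.copy()
            out["leading_edge"] = out["leading_edge"].map(
                lambda xs: "|".join(xs) if isinstance(xs, list) else ""
            )
            out.to_csv(outdir / "07_enrichment.tsv", sep="\t")
            curve_rows = [
                df.assign(set_id=sid) for sid, df in sorted(curves.items())
            ]
            if curve_rows:
                pd.concat(curve_rows)[["set_id", "rank", "running_sum"]].to_csv(
                    outdir / "07_curves.tsv", sep="\t", index=False
                )
            record("enrich", "07_enrichment.tsv", len(enr),
                   f"{len(enr)} sets scored, {len(skipped)} skipped, "
                   f"{int((enr['q_fdr'] < cfg.q_cut).sum())} at "
                   f"q < {cfg.q_cut}")
        else:
            record("enrich", "", 0, "no GMT supplied; enrichment skipped")

        if cfg.proteins:
            panel = ProteinPanel(
                values=pd.read_csv(cfg.proteins, sep="\t", index_col=0)
            )
            corr = correlate_matrix(
                filtered, panel,
                stratum=cfg.stratum or None,
                alpha_norm=cfg.alpha_norm,
            )
            corr.to_csv(outdir / "08_correlation.tsv", sep="\t", index=False)
            record("correlate", "08_correlation.tsv", len(corr),
                   f"{len(corr)} lipid-protein pairs")
        else:
            record("correlate", "", 0, "no protein panel; correlation skipped")
    except Exception as exc:
        log.error("run failed: %s", exc)
        manifest["failed"] = str(exc)
        with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2)
        handler.close()
        log.removeHandler(handler)
        raise
    manifest["completed"] = True
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    handler.close()
    log.removeHandler(handler)
    return outdir
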