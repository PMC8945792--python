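"""Deterministic synthetic study generator.

Emulates the statistical structure the pipeline assumes — a targeted
mediator panel quantified over a 2-tissue x 2-treatment x 2-protocol
design with a few replicates per cell — without any real acquisition:

* negative-binomial signals (variance ``mu + alpha mu^2``, matching the
  differential-abundance model) with log-uniform baseline means;
* treatment-spiked lipids whose DEP-group mean is shifted by a known
  log2 fold change;
* high-dropout lipids zeroed in a majority of samples to exercise the
  presence filter;
* spiked and decoy lipid sets written out as the four association-dump
  dialects (with planted malformed and duplicate rows);
* a six-marker protein panel with planted linear and monotone
  lipid-protein dependencies.

Everything derives from the config seed through named child streams, so
each artifact is byte-identical across runs and every planted effect is
recorded in truth tables sufficient to score downstream recovery.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .correlate import ProteinPanel
from .io import PROTOCOLS, SignalMatrix, TISSUES, TREATMENTS
from .registry import EnzymeClass, LipidRecord, LipidRegistry, Precursor, slugify
from .sets import (
    LipidSet,
    LipidSetCollection,
    build_collection,
    merge_collections,
    parse_association_dump,
    DIALECTS,
)

#: mediator names kept real for documentation parity
REAL_MEDIATORS = (
    ("Maresin-1", Precursor.DHA, EnzymeClass.LOX),
    ("9(10)-EpOME", Precursor.LA, EnzymeClass.CYP450),
    ("17-HDoHE", Precursor.DHA, EnzymeClass.LOX),
    ("13-OxoODE", Precursor.LA, EnzymeClass.LOX),
)

PROTEINS = ("HO-1", "iNOS", "Cyp1b1", "Hsp70", "COX2", "MPO")

DEFAULT_PRECURSOR_PROPORTIONS = {
    Precursor.AA: 0.30,
    Precursor.DHA: 0.20,
    Precursor.LA: 0.15,
    Precursor.EPA: 0.12,
    Precursor.DGLA: 0.08,
    Precursor.LNA: 0.07,
    Precursor.DPA: 0.05,
    Precursor.OTHER: 0.03,
}

_ENZYMES = (
    EnzymeClass.COX,
    EnzymeClass.LOX,
    EnzymeClass.CYP450,
    EnzymeClass.NON_ENZYMATIC,
    EnzymeClass.MIXED,
)


@dataclass
class SynthConfig:
    """Study conditions of the synthetic fixture.

    Defaults mirror a desk-scale version of the assumed design: ~100
    mediators over 24 samples (2 tissues x 2 treatments x 2 instillation
    protocols x 3 replicates), moderate NB dispersion, 4-fold treatment
    spikes, 3 coherently spiked sets against 20 decoys.
    """

    n_lipids: int = 100
    n_replicates: int = 3
    design: tuple[tuple[str, str, str], ...] = tuple(
        itertools.product(TISSUES, TREATMENTS, PROTOCOLS)
    )
    nb_mean_range: tuple[float, float] = (50.0, 500.0)
    dispersion: float = 0.1
    n_spiked_lipids: int = 10
    spike_log2fc: float = 2.0
    n_spiked_sets: int = 3
    spiked_set_size: tuple[int, int] = (10, 15)
    n_decoy_sets: int = 20
    decoy_set_size: tuple[int, int] = (10, 15)
    n_dropout_lipids: int = 5
    dropout_rate: float = 0.6
    precursor_proportions: dict = field(
        default_factory=lambda: dict(DEFAULT_PRECURSOR_PROPORTIONS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.n_spiked_lipids + self.n_dropout_lipids > self.n_lipids:
            raise ValueError("spiked + dropout lipids exceed n_lipids")

    def rng(self, stream: str) -> np.random.Generator:
        """Named child stream of the master seed."""
        return np.random.default_rng(
            np.random.SeedSequence([self.seed, abs(hash_stream(stream))])
        )


def hash_stream(name: str) -> int:
    # stable across processes (unlike built-in hash on str)
    import hashlib

    return int.from_bytes(
        hashlib.blake2b(name.encode(), digest_size=4).digest(), "big"
    )


@dataclass
class SynthTruth:
    """Planted effects, sufficient to score every downstream stage."""

    spiked_lipids: pd.DataFrame  # lipid, log2fc
    dropout_lipids: list[str]
    spiked_sets: list[str]
    decoy_sets: list[str]
    protein_pairs: pd.DataFrame  # protein, lipid, sign, kind
    base_means: pd.Series


# ------------------------------------------------------------------ registry


def make_registry(cfg: SynthConfig) -> LipidRegistry:
    """Synthetic mediator registry with plausible annotations.

    The first records are a fixed handful of real mediator names; the
    rest are synthetic with precursor proportions drawn from the
    configured marginals.
    """
    rng = cfg.rng("registry")
    reg = LipidRegistry()
    for name, prec, enz in REAL_MEDIATORS[: cfg.n_lipids]:
        reg.add(
            LipidRecord(
                canonical_id=slugify(name),
                display_name=name,
                precursor=prec,
                enzyme_class=enz,
            )
        )
    precs = list(cfg.precursor_proportions)
    probs = np.array([cfg.precursor_proportions[p] for p in precs], dtype=float)
    probs = probs / probs.sum()
    n_syn = cfg.n_lipids - len(reg)
    prec_draw = rng.choice(len(precs), size=n_syn, p=probs)
    enz_draw = rng.choice(len(_ENZYMES), size=n_syn)
    for k in range(n_syn):
        name = f"SynLM-{k + 1:03d}"
        reg.add(
            LipidRecord(
                canonical_id=slugify(name),
                display_name=name,
                synonyms=(f"synthetic mediator {k + 1}",),
                precursor=Precursor(precs[prec_draw[k]]),
                enzyme_class=_ENZYMES[enz_draw[k]],
            )
        )
    return reg


def _lipid_ids(cfg: SynthConfig) -> list[str]:
    return [rec.canonical_id for rec in make_registry(cfg)]


def _spike_plan(cfg: SynthConfig) -> tuple[list[str], list[str]]:
    """(spiked lipid ids, dropout lipid ids), disjoint, seed-determined."""
    rng = cfg.rng("plan")
    ids = np.array(_lipid_ids(cfg))
    picked = rng.choice(len(ids), size=cfg.n_spiked_lipids + cfg.n_dropout_lipids,
                        replace=False)
    spiked = sorted(ids[picked[: cfg.n_spiked_lipids]])
    dropout = sorted(ids[picked[cfg.n_spiked_lipids:]])
    return spiked, dropout


def design_meta(cfg: SynthConfig) -> pd.DataFrame:
    rows = []
    for tissue, treatment, protocol in cfg.design:
        for rep in range(1, cfg.n_replicates + 1):
            rows.append(
                {
                    "sample_id": f"{tissue}-{treatment}-{protocol}-{rep}",
                    "tissue": tissue,
                    "treatment": treatment,
                    "protocol": protocol,
                    "replicate": rep,
                }
            )
    return pd.DataFrame(rows).set_index("sample_id")


# ------------------------------------------------------------ signal matrix


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    if alpha == 0:
        return rng.poisson(mean).astype(float)
    r = 1.0 / alpha
    p = r / (r + mean)
    return rng.negative_binomial(r, p).astype(float)


def make_signal_matrix(cfg: SynthConfig) -> tuple[SignalMatrix, SynthTruth]:
    """NB signal matrix plus the truth tables for its planted effects."""
    rng = cfg.rng("matrix")
    ids = _lipid_ids(cfg)
    meta = design_meta(cfg)
    spiked, dropout = _spike_plan(cfg)

    lo, hi = cfg.nb_mean_range
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(ids)))
    base_means = pd.Series(base, index=ids, name="base_mean")

    mean = np.tile(base[:, None], (1, len(meta)))
    is_dep = (meta["treatment"] == "DEP").to_numpy()
    spike_rows = [ids.index(l) for l in spiked]
    for i in spike_rows:
        mean[i, is_dep] *= 2.0**cfg.spike_log2fc

    values = _nb_draw(rng, mean, cfg.dispersion)

    n_zero = int(round(cfg.dropout_rate * len(meta)))
    for lip in dropout:
        cols = rng.choice(len(meta), size=n_zero, replace=False)
        values[ids.index(lip), cols] = 0.0

    frame = pd.DataFrame(values, index=pd.Index(ids, name="lipid"),
                         columns=meta.index)
    truth = SynthTruth(
        spiked_lipids=pd.DataFrame(
            {"lipid": spiked, "log2fc": cfg.spike_log2fc}
        ),
        dropout_lipids=dropout,
        spiked_sets=[s.set_id for s in make_sets(cfg)[0]],
        decoy_sets=[s.set_id for s in make_sets(cfg)[1]],
        protein_pairs=_protein_truth(cfg),
        base_means=base_means,
    )
    return SignalMatrix(values=frame, meta=meta), truth


# --------------------------------------------------------------------- sets


def make_sets(cfg: SynthConfig) -> tuple[list[LipidSet], list[LipidSet]]:
    """(spiked sets, decoy sets) over the generated lipid ids.

    Spiked sets contain every treatment-spiked lipid (coherent 'up'
    direction) padded with unspiked fillers; decoys never touch a spiked
    or dropout lipid.
    """
    rng = cfg.rng("sets")
    ids = _lipid_ids(cfg)
    spiked, dropout = _spike_plan(cfg)
    clean = sorted(set(ids) - set(spiked) - set(dropout))
    sources = [s for s in DIALECTS if s != "custom"]

    spiked_sets = []
    for k in range(cfg.n_spiked_sets):
        size = int(rng.integers(cfg.spiked_set_size[0], cfg.spiked_set_size[1] + 1))
        n_fill = max(0, size - len(spiked))
        fill = list(rng.choice(clean, size=n_fill, replace=False))
        label = f"Spiked pathway {k + 1}"
        spiked_sets.append(
            LipidSet(
                set_id=slugify(label),
                description=label,
                members=tuple(sorted(set(spiked) | set(fill))),
                source=sources[k % len(sources)],
            )
        )
    decoys = []
    for k in range(cfg.n_decoy_sets):
        size = int(rng.integers(cfg.decoy_set_size[0], cfg.decoy_set_size[1] + 1))
        members = tuple(sorted(rng.choice(clean, size=size, replace=False)))
        label = f"Decoy pathway {k + 1}"
        decoys.append(
            LipidSet(
                set_id=slugify(label),
                description=label,
                members=members,
                source=sources[k % len(sources)],
            )
        )
    return spiked_sets, decoys


def expected_collection(cfg: SynthConfig) -> LipidSetCollection:
    spiked_sets, decoys = make_sets(cfg)
    return LipidSetCollection(sets=spiked_sets + decoys)


def make_association_dumps(
    cfg: SynthConfig, outdir: str | Path
) -> tuple[dict[str, Path], LipidSetCollection]:
    """Write one dump per source dialect; parsing them all back and
    building a collection reproduces :func:`expected_collection`.

    Each file carries one planted malformed row (missing lipid column)
    and one duplicated row, which the parser must count and tolerate.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    registry = make_registry(cfg)
    coll = expected_collection(cfg)
    by_source: dict[str, list[tuple[str, str]]] = {}
    for s in coll:
        for m in s.members:
            # dumps use display names to exercise synonym resolution
            by_source.setdefault(s.source, []).append(
                (s.description, registry.get(m).display_name)
            )
    paths = {}
    for source, pairs in sorted(by_source.items()):
        cols = DIALECTS[source]
        path = outdir / f"{source.lower()}_associations.tsv"
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("\t".join(cols) + "\n")
            for proc, lipid in pairs:
                ext = f"{source.upper()}:{slugify(lipid)}"
                fh.write("\t".join([proc, lipid, ext][: len(cols)]) + "\n")
            # planted duplicate of the first association
            proc, lipid = pairs[0]
            fh.write("\t".join([proc, lipid, "dup"][: len(cols)]) + "\n")
            # planted malformed row: process label but no lipid
            fh.write(pairs[0][0] + "\t\n")
        paths[source] = path
    return paths, coll


def rebuild_collection_from_dumps(
    cfg: SynthConfig, dump_paths: dict[str, Path]
) -> LipidSetCollection:
    """Parse every dump and build the collection the pipeline would use."""
    registry = make_registry(cfg)
    built = []
    for source, path in sorted(dump_paths.items()):
        table = parse_association_dump(path, source)
        built.append(
            build_collection(
                table.pairs,
                registry,
                min_size=1,
                max_size=10**6,
                source=source,
            )
        )
    return merge_collections(built)


# ------------------------------------------------------------ protein panel


def _protein_truth(cfg: SynthConfig) -> pd.DataFrame:
    spiked, _ = _spike_plan(cfg)
    ids = _lipid_ids(cfg)
    _, dropout = _spike_plan(cfg)
    clean = sorted(set(ids) - set(spiked) - set(dropout))
    # deterministic anchor lipids for the planted dependencies
    anchors = clean[:3]
    return pd.DataFrame(
        {
            "protein": ["HO-1", "iNOS", "COX2"],
            "lipid": anchors,
            "sign": [1, 1, -1],
            "kind": ["linear", "monotone", "monotone"],
        }
    )


def make_protein_panel(
    cfg: SynthConfig, matrix: SignalMatrix
) -> tuple[ProteinPanel, pd.DataFrame]:
    """Six-marker immunoblot-like panel with planted dependencies.

    HO-1 is linear in its anchor lipid, iNOS monotone-nonlinear
    (detectable by the Spearman branch), COX2 negatively monotone;
    Cyp1b1, Hsp70 and MPO are independent noise.
    """
    rng = cfg.rng("proteins")
    truth = _protein_truth(cfg)
    samples = matrix.samples
    values = {}
    for protein in PROTEINS:
        row = truth[truth["protein"] == protein]
        if row.empty:
            values[protein] = rng.lognormal(mean=0.0, sigma=0.4, size=len(samples))
            continue
        lip = row["lipid"].iloc[0]
        x = matrix.values.loc[lip].to_numpy(dtype=float)
        z = (x - x.mean()) / (x.std() + 1e-12)
        noise = rng.normal(0, 0.05, size=len(samples))
        kind, sign = row["kind"].iloc[0], int(row["sign"].iloc[0])
        if kind == "linear":
            values[protein] = 5.0 + sign * (2.0 * z) + noise
        else:
            values[protein] = np.exp(sign * (0.8 * z) + noise)
    panel = pd.DataFrame(values, index=samples).T.clip(lower=0.0)
    panel.index.name = "protein"
    return ProteinPanel(values=panel), truth


# --------------------------------------------------------------- file bundle


@dataclass
class FixtureBundle:
    matrix: SignalMatrix
    registry: LipidRegistry
    collection: LipidSetCollection
    panel: ProteinPanel
    truth: SynthTruth
    paths: dict[str, Path] = field(default_factory=dict)


def generate(cfg: SynthConfig, outdir: str | Path | None = None) -> FixtureBundle:
    """Generate the full fixture; optionally write every file format."""
    from .sets import write_gmt

    registry = make_registry(cfg)
    matrix, truth = make_signal_matrix(cfg)
    coll = expected_collection(cfg)
    panel, _ = make_protein_panel(cfg, matrix)
    paths: dict[str, Path] = {}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths["values"] = outdir / "values.tsv"
        matrix.values.to_csv(paths["values"], sep="\t")
        paths["meta"] = outdir / "meta.tsv"
        matrix.meta.to_csv(paths["meta"], sep="\t")
        paths["registry"] = outdir / "registry.tsv"
        registry.to_tsv(paths["registry"])
        paths["gmt"] = outdir / "sets.gmt"
        write_gmt(coll, paths["gmt"])
        paths["proteins"] = outdir / "proteins.tsv"
        panel.values.to_csv(paths["proteins"], sep="\t")
        dump_paths, _ = make_association_dumps(cfg, outdir / "dumps")
        paths.update({f"dump_{k}": v for k, v in dump_paths.items()})
    return FixtureBundle(
        matrix=matrix, registry=registry, collection=coll, panel=panel,
        truth=truth, paths=paths,
    )
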