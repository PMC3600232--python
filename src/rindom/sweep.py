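"""Parameter-sweep harness: strategies x cutoffs x methods over a manifest.

Runs the full pipeline (network -> community division -> cut at the annotated
domain count -> Acc) for every structure in a manifest and every grid cell,
and aggregates per-cell mean accuracies in the layout of the published-style
threshold/accuracy tables (with a step-size dimension for the random-walk
method).  A stability mode re-runs the sweep on nested random subsets of the
manifest to probe how sensitive the optimum is to dataset size.

Everything is deterministic: re-running with the same manifest, config and
seed is bit-identical.
"""

from __future__ import annotations

import csv
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .community import DEFAULT_STEP_GRID, Method
from .evaluate import (
    DomainAnnotation,
    EvaluationResult,
    evaluate_structure,
    read_annotation_tsv,
)
from .network import DEFAULT_CUTOFF_GRIDS, NetworkBuildConfig
from .structure_io import StructureError, VertexStrategy, parse_pdb

logger = logging.getLogger(__name__)


@dataclass
class SweepConfig:
    """Grid definition for a sweep.

    Defaults reproduce the standard grids: Ca and centroid cutoffs 3-10 A in
    0.5 A steps (15 values each), any-atom surface-gap cutoffs 0-6 A in 0.5 A
    steps (13 values), and random-walk lengths 3-10.
    """

    strategies: list[VertexStrategy] = field(
        default_factory=lambda: list(VertexStrategy)
    )
    cutoffs: dict[VertexStrategy, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_CUTOFF_GRIDS)
    )
    methods: list[Method] = field(default_factory=lambda: list(Method))
    steps_grid: tuple[int, ...] = DEFAULT_STEP_GRID
    subsample_sizes: tuple[int, ...] = ()
    subsample_seed: int = 0
    weighted_mean: bool = False
    mapping: str = "matching"

    def __post_init__(self) -> None:
        self.strategies = [VertexStrategy(s) for s in self.strategies]
        self.methods = [Method(m) for m in self.methods]
        self.cutoffs = {
            VertexStrategy(s): tuple(v) for s, v in self.cutoffs.items()
        }
        for strat in self.strategies:
            if not self.cutoffs.get(strat):
                raise ValueError(f"empty cutoff grid for {strat.value}")
        if not (self.strategies and self.methods and len(self.steps_grid)):
            raise ValueError("strategies, methods and steps grid must be non-empty")

    def cells(self) -> list[tuple[VertexStrategy, float, Method, int | None]]:
        """All grid cells in deterministic order."""
        out: list[tuple[VertexStrategy, float, Method, int | None]] = []
        for method in self.methods:
            for strat in self.strategies:
                for cutoff in self.cutoffs[strat]:
                    if method is Method.RANDOM_WALK:
                        out.extend(
                            (strat, cutoff, method, t) for t in self.steps_grid
                        )
                    else:
                        out.append((strat, cutoff, method, None))
        return out

    @classmethod
    def from_toml(cls, path: str | Path) -> "SweepConfig":
        """Load a sweep configuration from a TOML file.

        Recognised keys: ``strategies`` (list), ``methods`` (list),
        ``steps_grid`` (list of ints), ``subsample_sizes``, ``subsample_seed``,
        ``weighted_mean``, ``mapping`` and a ``[cutoffs]`` table mapping
        strategy name to a list of cutoffs.
        """
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        kwargs: dict = {}
        if "strategies" in raw:
            kwargs["strategies"] = [VertexStrategy(s) for s in raw["strategies"]]
        if "methods" in raw:
            kwargs["methods"] = [Method(m) for m in raw["methods"]]
        if "cutoffs" in raw:
            cutoffs = dict(DEFAULT_CUTOFF_GRIDS)
            for name, grid in raw["cutoffs"].items():
                cutoffs[VertexStrategy(name)] = tuple(float(c) for c in grid)
            kwargs["cutoffs"] = cutoffs
        for key in ("subsample_seed", "weighted_mean", "mapping"):
            if key in raw:
                kwargs[key] = raw[key]
        if "steps_grid" in raw:
            kwargs["steps_grid"] = tuple(int(t) for t in raw["steps_grid"])
        if "subsample_sizes" in raw:
            kwargs["subsample_sizes"] = tuple(int(s) for s in raw["subsample_sizes"])
        return cls(**kwargs)


@dataclass
class ManifestEntry:
    pdb_path: Path
    annotation: DomainAnnotation
    chain_ids: list[str] | None = None


def read_manifest(path: str | Path) -> list[ManifestEntry]:
    """Read a manifest TSV with columns ``pdb_path`` and ``annotation_path``
    (paths resolved relative to the manifest file)."""
    base = Path(path).parent
    entries: list[ManifestEntry] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            pdb_path = (base / row["pdb_path"]).resolve()
            annotations = read_annotation_tsv((base / row["annotation_path"]).resolve())
            for ann in annotations.values():
                entries.append(ManifestEntry(pdb_path, ann))
    if not entries:
        raise ValueError(f"manifest {path} is empty")
    return entries


# ---------------------------------------------------------------------------
# Sweep execution

_PER_PROTEIN_COLUMNS = [
    "structure_id", "strategy", "cutoff", "method", "steps",
    "k", "n_domain_residues", "accuracy", "status",
]


def run_sweep(
    entries: list[ManifestEntry], config: SweepConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Evaluate every manifest entry at every grid cell.

    Returns ``(per_protein, aggregate)`` tables.  Structures that fail to
    parse are logged and reported with status ``parse_error`` (accuracy NaN);
    aggregate rows carry both the evaluated and the total structure counts so
    failures are never silently dropped.
    """
    if not entries:
        raise ValueError("empty manifest")
    models = []
    for entry in entries:
        try:
            model = parse_pdb(
                entry.pdb_path, structure_id=entry.annotation.structure_id
            )
        except (StructureError, OSError) as exc:
            logger.warning("skipping %s: %s", entry.pdb_path, exc)
            model = None
        models.append(model)

    rows: list[dict] = []
    for strat, cutoff, method, steps in config.cells():
        build_cfg = NetworkBuildConfig(strategy=strat, cutoff=cutoff)
        for entry, model in zip(entries, models):
            base = {
                "structure_id": entry.annotation.structure_id,
                "strategy": strat.value,
                "cutoff": cutoff,
                "method": method.value,
                "steps": steps,
            }
            if model is None:
                rows.append(
                    base | {"k": None, "n_domain_residues": None,
                            "accuracy": np.nan, "status": "parse_error"}
                )
                continue
            try:
                result = evaluate_structure(
                    model, entry.annotation, build_cfg, method,
                    steps=steps, chain_ids=entry.chain_ids,
                    mapping=config.mapping,
                )
            except Exception as exc:  # annotation/network errors
                logger.warning(
                    "%s @ %s/%.1f/%s: %s",
                    entry.annotation.structure_id, strat.value, cutoff,
                    method.value, exc,
                )
                rows.append(
                    base | {"k": None, "n_domain_residues": None,
                            "accuracy": np.nan, "status": "error"}
                )
                continue
            logger.info(
                "%s %s %.1f %s steps=%s: Acc=%.2f%%",
                result.structure_id, strat.value, cutoff, method.value,
                steps, result.accuracy,
            )
            rows.append(
                base | {"k": result.k,
                        "n_domain_residues": result.n_domain_residues,
                        "accuracy": result.accuracy, "status": "ok"}
            )
    per_protein = pd.DataFrame(rows, columns=_PER_PROTEIN_COLUMNS)
    aggregate = aggregate_table(per_protein, weighted=config.weighted_mean)
    return per_protein, aggregate


def aggregate_table(per_protein: pd.DataFrame, weighted: bool = False) -> pd.DataFrame:
    """Mean accuracy per grid cell (threshold x accuracy table layout)."""
    rows = []
    keys = ["strategy", "cutoff", "method", "steps"]
    for cell, group in per_protein.groupby(keys, dropna=False, sort=True):
        ok = group[group["status"] == "ok"]
        if len(ok) and weighted:
            wsum = ok["n_domain_residues"].sum()
            acc = float((ok["accuracy"] * ok["n_domain_residues"]).sum() / wsum)
        elif len(ok):
            acc = float(ok["accuracy"].mean())
        else:
            acc = np.nan
        rows.append(dict(zip(keys, cell)) | {
            "mean_accuracy": acc,
            "n_evaluated": len(ok),
            "n_total": len(group),
        })
    return pd.DataFrame(rows)


def run_stability(
    entries: list[ManifestEntry],
    config: SweepConfig,
) -> pd.DataFrame:
    """Stability mode: sweep nested random subsets of the manifest.

    Subsets are nested (each size extends the previous) and drawn from a
    permutation seeded by ``config.subsample_seed``.  Returns the concatenated
    aggregate tables with a ``subset_size`` column.
    """
    if not config.subsample_sizes:
        raise ValueError("stability mode requires subsample_sizes")
    sizes = sorted(set(config.subsample_sizes))
    if sizes[-1] > len(entries):
        raise ValueError(
            f"largest subset ({sizes[-1]}) exceeds manifest size ({len(entries)})"
        )
    rng = np.random.default_rng(config.subsample_seed)
    order = rng.permutation(len(entries))
    blocks = []
    for size in sizes:
        subset = [entries[i] for i in order[:size]]
        _, aggregate = run_sweep(subset, config)
        aggregate.insert(0, "subset_size", size)
        blocks.append(aggregate)
    return pd.concat(blocks, ignore_index=True)
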