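"""Full factorial sweep over culture ratios, tie counts, mechanisms and
replicates, with per-cell aggregation of the outcome identifications.

The default grid is 9 ratios x 8 tie counts x (positive + negative + 11
mixed alphas) x 50 replicates: 936 cells, 46,800 runs.  Per-run seeds are
derived from the cell coordinates and replicate index through a stable
counter-based hash (``numpy.random.SeedSequence``), so streams never shift
when axes are added or cells run out of order.
"""

from __future__ import annotations

import logging
import math
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .ego_network import generate_network
from .identity_dynamics import (
    Mechanism,
    MechanismKind,
    SimulationConfig,
    final_state,
    simulate,
)

__all__ = [
    "GridSpec",
    "Cell",
    "RunRecord",
    "SummaryRow",
    "default_mechanisms",
    "enumerate_cells",
    "run_seed",
    "run_sweep",
    "summarize",
    "records_to_frame",
    "summary_to_frame",
]

logger = logging.getLogger(__name__)

DEFAULT_TIE_COUNTS = tuple(range(0, 29, 4))  # 0, 4, ..., 28


def default_mechanisms() -> tuple[Mechanism, ...]:
    """Positive, negative, and mixed at alpha = 0.0, 0.1, ..., 1.0.

    Both alpha endpoints are kept even though they duplicate the pure
    mechanisms; the full default design therefore counts
    9 * 8 * (1 + 1 + 11) * 50 = 46,800 runs.
    """
    mixed = tuple(
        Mechanism(MechanismKind.MIXED, alpha=round(k * 0.1, 1)) for k in range(11)
    )
    return (Mechanism(MechanismKind.POSITIVE), Mechanism(MechanismKind.NEGATIVE)) + mixed


@dataclass(frozen=True)
class GridSpec:
    n_alters: int = 8
    ratios: tuple[int, ...] = tuple(range(9))
    tie_counts: tuple[int, ...] = DEFAULT_TIE_COUNTS
    mechanisms: tuple[Mechanism, ...] = field(default_factory=default_mechanisms)
    replicates: int = 50
    config: SimulationConfig = field(default_factory=SimulationConfig)
    base_seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "ratios", tuple(self.ratios))
        object.__setattr__(self, "tie_counts", tuple(self.tie_counts))
        object.__setattr__(self, "mechanisms", tuple(self.mechanisms))
        if not self.ratios or not self.tie_counts or not self.mechanisms:
            raise ValueError("every grid axis must be non-empty")
        if self.replicates < 1:
            raise ValueError(f"replicates must be >= 1, got {self.replicates}")
        max_ties = self.n_alters * (self.n_alters - 1) // 2
        for r in self.ratios:
            if not 0 <= r <= self.n_alters:
                raise ValueError(f"ratio {r} outside [0, {self.n_alters}]")
        for t in self.tie_counts:
            if not 0 <= t <= max_ties:
                raise ValueError(f"tie count {t} outside [0, {max_ties}]")


@dataclass(frozen=True)
class Cell:
    mechanism_index: int
    mechanism: Mechanism
    ratio: int
    ties: int


@dataclass(frozen=True)
class RunRecord:
    ratio: int
    ties: int
    mechanism_kind: str
    alpha: Optional[float]
    replicate: int
    seed: int
    final_id_a: float
    final_id_b: float


@dataclass(frozen=True)
class SummaryRow:
    ratio: int
    ties: int
    mechanism_kind: str
    alpha: Optional[float]
    mean_id_a: float
    sd_id_a: Optional[float]
    mean_id_b: float
    sd_id_b: Optional[float]
    n_replicates: int


def enumerate_cells(grid: GridSpec) -> list[Cell]:
    """Deterministic cell order: mechanism, then ratio, then tie count."""
    return [
        Cell(mechanism_index=m, mechanism=mech, ratio=r, ties=t)
        for m, mech in enumerate(grid.mechanisms)
        for r in grid.ratios
        for t in grid.tie_counts
    ]


def run_seed(
    base_seed: int, mechanism_index: int, ratio: int, ties: int, replicate: int
) -> int:
    """Stable per-run seed mixed from the cell coordinates and replicate.

    Uses SeedSequence's hash so adjacent coordinates give uncorrelated
    streams and adding cells never shifts the seeds of existing ones.
    """
    ss = np.random.SeedSequence([base_seed, mechanism_index, ratio, ties, replicate])
    return int(ss.generate_state(2, dtype=np.uint64)[0])


def run_sweep(grid: GridSpec) -> list[RunRecord]:
    """Execute every (cell, replicate): fresh network per replicate (culture
    counts fixed, tie placement redrawn), one 50-step simulation, finals
    recorded.  Bit-identical when re-run with the same ``base_seed``."""
    cells = enumerate_cells(grid)
    records: list[RunRecord] = []
    for k, cell in enumerate(cells):
        logger.info(
            "cell %d/%d: mechanism=%s ratio=%d ties=%d",
            k + 1,
            len(cells),
            cell.mechanism.label,
            cell.ratio,
            cell.ties,
        )
        alpha = cell.mechanism.alpha
        kind = cell.mechanism.kind.value
        for rep in range(grid.replicates):
            seed = run_seed(
                grid.base_seed, cell.mechanism_index, cell.ratio, cell.ties, rep
            )
            rng = np.random.default_rng(seed)
            try:
                network = generate_network(
                    grid.n_alters, cell.ratio, cell.ties, rng=rng
                )
                trajectory = simulate(network, cell.mechanism, grid.config, rng=rng)
            except Exception as exc:
                raise RuntimeError(
                    f"sweep failed in cell mechanism={cell.mechanism.label} "
                    f"ratio={cell.ratio} ties={cell.ties} replicate={rep}: {exc}"
                ) from exc
            outcome = final_state(trajectory)
            records.append(
                RunRecord(
                    ratio=cell.ratio,
                    ties=cell.ties,
                    mechanism_kind=kind,
                    alpha=alpha,
                    replicate=rep,
                    seed=seed,
                    final_id_a=outcome.id_a,
                    final_id_b=outcome.id_b,
                )
            )
    return records


def summarize(records: Sequence[RunRecord]) -> list[SummaryRow]:
    """Per-cell mean and sample (n-1) standard deviation of the finals.

    Groups by (mechanism_kind, alpha, ratio, ties) in first-seen order; a
    single-replicate cell reports its SDs as ``None``.
    """
    if not records:
        raise ValueError("no records to summarize")
    groups: dict[tuple, list[RunRecord]] = {}
    for rec in records:
        groups.setdefault(
            (rec.mechanism_kind, rec.alpha, rec.ratio, rec.ties), []
        ).append(rec)
    rows = []
    for (kind, alpha, ratio, ties), group in groups.items():
        a_vals = [r.final_id_a for r in group]
        b_vals = [r.final_id_b for r in group]
        n = len(group)
        rows.append(
            SummaryRow(
                ratio=ratio,
                ties=ties,
                mechanism_kind=kind,
                alpha=alpha,
                mean_id_a=statistics.fmean(a_vals),
                sd_id_a=statistics.stdev(a_vals) if n > 1 else None,
                mean_id_b=statistics.fmean(b_vals),
                sd_id_b=statistics.stdev(b_vals) if n > 1 else None,
                n_replicates=n,
            )
        )
    return rows


def records_to_frame(records: Sequence[RunRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "ratio": [r.ratio for r in records],
            "ties": [r.ties for r in records],
            "mechanism_kind": [r.mechanism_kind for r in records],
            "alpha": [r.alpha for r in records],
            "replicate": [r.replicate for r in records],
            "seed": [r.seed for r in records],
            "final_id_a": [r.final_id_a for r in records],
            "final_id_b": [r.final_id_b for r in records],
        }
    )


def summary_to_frame(rows: Sequence[SummaryRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "ratio": [r.ratio for r in rows],
            "ties": [r.ties for r in rows],
            "mechanism_kind": [r.mechanism_kind for r in rows],
            "alpha": [r.alpha for r in rows],
            "mean_id_a": [r.mean_id_a for r in rows],
            "sd_id_a": [r.sd_id_a for r in rows],
            "mean_id_b": [r.mean_id_b for r in rows],
            "sd_id_b": [r.sd_id_b for r in rows],
            "n_replicates": [r.n_replicates for r in rows],
        }
    )
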