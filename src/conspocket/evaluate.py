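"""Benchmark harness: the 4-A hit criterion and TOP-N success rates.

A ranked prediction scores a hit at rank *r* when the r-th pocket's
geometric center lies within a cutoff (default 4 A, inclusive) of any
atom of any bound ligand — the PocketPicker criterion.  TOP-N success is
the fraction of evaluated structures whose best hit rank is <= N.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .conservation import ConservationMap, parse_grades
from .errors import EvaluationError
from .pockets import PredictionTrace, predict_pockets
from .scoring import RankedPrediction, rank_pockets
from .structure import Atom, ProteinComplex, read_pdb
from .surface import compute_sasa

log = logging.getLogger(__name__)

DEFAULT_HIT_CUTOFF = 4.0  # Angstrom, inclusive


@dataclass
class HitRecord:
    """Hit/miss outcome for one structure's ranked prediction."""

    structure_id: str
    ranks_hit: frozenset[int]
    n_pockets: int = 0

    @property
    def top1_hit(self) -> bool:
        return self.topn_hit(1)

    @property
    def top3_hit(self) -> bool:
        return self.topn_hit(3)

    def topn_hit(self, n: int) -> bool:
        return bool(self.ranks_hit) and min(self.ranks_hit) <= n


@dataclass
class BenchmarkResult:
    """Aggregate TOP-N rates plus the per-structure hit table."""

    records: list[HitRecord]
    n_skipped: int = 0
    skipped_ids: list[str] = field(default_factory=list)

    @property
    def n_evaluated(self) -> int:
        return len(self.records)

    def topn_rate(self, n: int) -> float:
        if not self.records:
            raise EvaluationError("no structures were evaluated")
        return sum(r.topn_hit(n) for r in self.records) / len(self.records)

    @property
    def top1_rate(self) -> float:
        return self.topn_rate(1)

    @property
    def top3_rate(self) -> float:
        return self.topn_rate(3)

    def per_structure_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "structure_id": [r.structure_id for r in self.records],
                "n_pockets": [r.n_pockets for r in self.records],
                "best_hit_rank": [
                    min(r.ranks_hit) if r.ranks_hit else 0 for r in self.records
                ],
                "top1_hit": [r.top1_hit for r in self.records],
                "top3_hit": [r.top3_hit for r in self.records],
            }
        )


def is_hit(
    center: np.ndarray,
    ligand_atoms: Sequence[Atom],
    cutoff: float = DEFAULT_HIT_CUTOFF,
) -> bool:
    """True iff ``center`` lies within ``cutoff`` (inclusive) of any
    ligand atom center."""
    if not ligand_atoms:
        raise EvaluationError("hit test needs at least one ligand atom")
    lig = np.array([a.coords for a in ligand_atoms])
    d = np.linalg.norm(lig - np.asarray(center, dtype=float), axis=1)
    return bool(d.min() <= cutoff)


def evaluate_structure(
    prediction: RankedPrediction,
    complex_: ProteinComplex,
    cutoff: float = DEFAULT_HIT_CUTOFF,
) -> HitRecord:
    """Test every ranked pocket against every ligand group of the complex.

    A rank is a hit if any ligand group satisfies the criterion; an empty
    prediction yields an all-miss record.
    """
    ranks_hit = set()
    for pocket in prediction.pockets:
        for group in complex_.ligand_groups:
            if is_hit(pocket.center, group.atoms, cutoff):
                ranks_hit.add(pocket.rank)
                break
    return HitRecord(
        structure_id=prediction.structure_id or complex_.source_id,
        ranks_hit=frozenset(ranks_hit),
        n_pockets=len(prediction.pockets),
    )


def _predict_and_rank(
    complex_: ProteinComplex,
    cmap: ConservationMap | None,
    method: str,
    hit_cutoff: float,
    predict_kwargs: dict,
) -> HitRecord:
    pockets = predict_pockets(complex_, cmap, **predict_kwargs)
    atoms_by_serial = {a.serial: a for a in complex_.protein_atoms}
    ranked = rank_pockets(
        pockets,
        method=method,
        cmap=cmap,
        atoms_by_serial=atoms_by_serial,
        structure_id=complex_.source_id,
    )
    return evaluate_structure(ranked, complex_, hit_cutoff)


def benchmark(
    dataset: Iterable[tuple[str, str]],
    method: str = "conservation",
    hit_cutoff: float = DEFAULT_HIT_CUTOFF,
    **predict_kwargs,
) -> BenchmarkResult:
    """Run the full pipeline over (pdb_path, grades_path) pairs and
    aggregate TOP-N rates.

    A structure whose prediction runs and returns zero pockets counts as
    a miss in the denominator; a structure whose inputs fail to load or
    that has no ligand to evaluate against is *skipped* and reported
    separately, so denominators stay auditable.
    """
    records: list[HitRecord] = []
    skipped: list[str] = []
    for pdb_path, grades_path in dataset:
        try:
            cplx = read_pdb(pdb_path)
            cmap = parse_grades(grades_path) if grades_path else None
            if not cplx.ligand_groups:
                raise EvaluationError(f"{cplx.source_id}: no ligand to evaluate against")
            records.append(
                _predict_and_rank(cplx, cmap, method, hit_cutoff, predict_kwargs)
            )
        except EvaluationError as exc:
            log.warning("skipping structure: %s", exc)
            skipped.append(str(pdb_path))
        except Exception as exc:  # unreadable inputs: skip, do not abort the run
            log.warning("skipping %s: %s: %s", pdb_path, type(exc).__name__, exc)
            skipped.append(str(pdb_path))
    if not records:
        raise EvaluationError("all structures were skipped; nothing evaluated")
    return BenchmarkResult(records=records, n_skipped=len(skipped), skipped_ids=skipped)


@dataclass
class SweepResult:
    """TOP-N rates on a (expand_dist x conservation_cutoff) grid."""

    grid: dict[tuple[float, int | None], tuple[float, float]]
    flagged_empty: set[tuple[float, int | None]] = field(default_factory=set)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (expand, cutoff), (t1, t3) in sorted(
            self.grid.items(), key=lambda kv: (kv[0][0], -1 if kv[0][1] is None else kv[0][1])
        ):
            rows.append(
                {
                    "expand_dist": expand,
                    "conservation_cutoff": "none" if cutoff is None else cutoff,
                    "top1_rate": t1,
                    "top3_rate": t3,
                    "empty_potential_flag": (expand, cutoff) in self.flagged_empty,
                }
            )
        return pd.DataFrame(rows)


def parameter_sweep(
    dataset: Sequence[tuple[str, str]],
    expand_dists: Sequence[float],
    cutoffs: Sequence[int | None],
    method: str = "conservation",
    hit_cutoff: float = DEFAULT_HIT_CUTOFF,
    **predict_kwargs,
) -> SweepResult:
    """Full-factorial sweep of expansion distance x conservation cutoff.

    A ``None`` cutoff disables the conservation filter (P = cleft).
    Per-atom SASA does not depend on either swept factor, so it is
    computed once per structure and reused across cells.  Cells where any
    structure yields zero potential atoms are flagged — with a strict
    cutoff the candidate set can become too small to form any pocket.
    """
    loaded = []
    for pdb_path, grades_path in dataset:
        try:
            cplx = read_pdb(pdb_path)
            cmap = parse_grades(grades_path) if grades_path else None
            if not cplx.ligand_groups:
                raise EvaluationError("no ligand")
            from .structure import assign_radii

            assign_radii(cplx.protein_atoms, predict_kwargs.get("radius_set", "chothia"))
            sasa = compute_sasa(
                cplx.protein_atoms,
                probe=predict_kwargs.get("sasa_probe", 1.4),
                n_points=predict_kwargs.get("sasa_points", 960),
            )
            loaded.append((cplx, cmap, sasa))
        except Exception as exc:
            log.warning("sweep: skipping %s: %s", pdb_path, exc)
    if not loaded:
        raise EvaluationError("all structures were skipped; nothing to sweep")
    grid: dict[tuple[float, int | None], tuple[float, float]] = {}
    flagged: set[tuple[float, int | None]] = set()
    for expand in expand_dists:
        for cutoff in cutoffs:
            records = []
            for cplx, cmap, sasa in loaded:
                trace = PredictionTrace()
                kwargs = dict(predict_kwargs)
                kwargs.update(
                    expand_dist=expand, conservation_cutoff=cutoff, sasa=sasa, trace=trace
                )
                pockets = predict_pockets(cplx, cmap, **kwargs)
                if trace.n_potential == 0:
                    flagged.add((expand, cutoff))
                atoms_by_serial = {a.serial: a for a in cplx.protein_atoms}
                ranked = rank_pockets(
                    pockets, method=method, cmap=cmap,
                    atoms_by_serial=atoms_by_serial, structure_id=cplx.source_id,
                )
                records.append(evaluate_structure(ranked, cplx, hit_cutoff))
            res = BenchmarkResult(records=records)
            grid[(expand, cutoff)] = (res.top1_rate, res.top3_rate)
    return SweepResult(grid=grid, flagged_empty=flagged)
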