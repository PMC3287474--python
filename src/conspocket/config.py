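"""Run configuration: every tunable of the pipeline in one place."""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields

from .errors import ParameterError


@dataclass
class RunConfig:
    """All pipeline parameters with their default values.

    Stated algorithm parameters: 6.5 A hull expansion, conservation
    cutoff 7 on the 1-9 scale, 8 A center merge, 4 A inclusive hit
    cutoff.  The rest are this implementation's defaults: 1.4 A water
    probe, 960 deterministic sphere points, 1 A^2 surface threshold,
    4.5 A atom-link distance, 3-atom minimum pocket size, 1 A volume
    grid.
    """

    sasa_probe: float = 1.4
    sasa_points: int = 960
    sasa_threshold: float = 1.0
    expand_dist: float = 6.5
    conservation_cutoff: int | None = 7
    atom_link_dist: float = 4.5
    center_merge_dist: float = 8.0
    min_pocket_atoms: int = 3
    rank_method: str = "conservation"
    hit_cutoff: float = 4.0
    volume_grid: float = 1.0

    def __post_init__(self) -> None:
        for name in ("sasa_probe", "expand_dist", "atom_link_dist",
                     "center_merge_dist", "hit_cutoff", "volume_grid"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.conservation_cutoff is not None and not (1 <= self.conservation_cutoff <= 9):
            raise ParameterError("conservation_cutoff must be in [1, 9] or None")
        if self.rank_method not in ("conservation", "volume"):
            raise ParameterError(f"unknown rank_method {self.rank_method!r}")

    def predict_kwargs(self) -> dict:
        """Keyword arguments for :func:`conspocket.pockets.predict_pockets`."""
        return {
            "sasa_probe": self.sasa_probe,
            "sasa_points": self.sasa_points,
            "sasa_threshold": self.sasa_threshold,
            "expand_dist": self.expand_dist,
            "conservation_cutoff": self.conservation_cutoff,
            "atom_link_dist": self.atom_link_dist,
            "center_merge_dist": self.center_merge_dist,
            "min_pocket_atoms": self.min_pocket_atoms,
        }

    def header_lines(self) -> list[str]:
        """Provenance header embedded in every report file."""
        return [f"# {k} = {v}" for k, v in asdict(self).items()]
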