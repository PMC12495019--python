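"""Pipeline configuration: every tunable parameter with its printed default."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """All pipeline parameters; defaults follow the tuned analysis protocol.

    Units: pixel-based structuring elements are in px (tuned for
    ~0.5-0.6 um/px imagery); profile intervals are in um.
    """

    # imaging
    channel_map: dict[str, int] = field(
        default_factory=lambda: {"dapi": 0, "protein_a": 1, "protein_b": 2}
    )
    pixel_size_um: float = 0.57

    # focal correction
    focal_degree: int = 5

    # segmentation
    sigma_n: float = 3.0  # px, DAPI smoothing
    r_n: int = 9  # px, background structuring radius
    kill_radius: int = 2  # px, nuclear kill zone for the cell watershed

    # edge profiling (um)
    bin_um: float = 5.0
    proximal_um: tuple[float, float] = (5.0, 30.0)
    distal_um: tuple[float, float] = (50.0, 80.0)
    domain_um: tuple[float, float] = (0.0, 80.0)
    border_x: float | None = None  # px column; None disables profiling

    # colocalization
    tile: int = 8
    n_perm: int = 200
    quantile_step: float = 0.1
    hnf_threshold: float = 0.5
    hnf_min_cells: int = 5

    # reproducibility
    seed: int = 0
    out_dir: str = "epifocal_out"

    def __post_init__(self) -> None:
        p, d = self.proximal_um, self.distal_um
        if not (p[0] < p[1] <= d[0] < d[1]):
            raise ValueError("proximal/distal intervals must be ordered and disjoint")
        if self.focal_degree < 1:
            raise ValueError("focal_degree must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["proximal_um"] = list(self.proximal_um)
        d["distal_um"] = list(self.distal_um)
        d["domain_um"] = list(self.domain_um)
        return d

    def config_hash(self) -> str:
        """Short stable hash identifying this parameter set in output files."""
        blob = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update(overrides)
        for key in ("proximal_um", "distal_um", "domain_um"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)
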