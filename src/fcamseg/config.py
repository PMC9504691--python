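"""Run configuration with the pipeline's default settings.

Defaults: 400 superpixels, compactness 1, 1000 prototypes per class, a
2x4x2 Gaussian fuzzy palette (16 colors, the G channel favored as a
luminance proxy), Chebyshev neighborhood radius 1, refinement threshold
0.5% of the image, and a training-patch half-width derived from the
image size and superpixel count unless given explicitly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import InvalidParameterError
from .fuzzy_color import build_palette
from .segmenter import patch_halfwidth

log = logging.getLogger("fcamseg")

CONTRACT_VERSION = "1.0"  # frozen metric/convention contract


@dataclass
class RunConfig:
    palette_counts: tuple[int, int, int] = (2, 4, 2)
    palette_kind: str = "gaussian"
    zeta: float = 2.0
    P: int = 400
    m: float = 1.0
    T: int = 1000
    W: int | None = None  # None: derive from image size and P
    radius: int = 1
    prototype_seed: int = 0
    elm_seed: int = 0
    refine: bool = True
    min_frac: float = 0.005

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load from a flat YAML or JSON key-value document."""
        text = Path(path).read_text()
        data = yaml.safe_load(text) if not str(path).endswith(".json") else json.loads(text)
        if not isinstance(data, dict):
            raise InvalidParameterError(f"{path}: expected a flat mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        if "palette_counts" in data:
            data["palette_counts"] = tuple(data["palette_counts"])
        return cls(**data)

    def resolved(self, image_shape=None) -> dict:
        """Full resolved settings, including derived quantities, enough
        to reproduce a run bit-for-bit."""
        pal = build_palette(self.palette_counts, self.palette_kind, self.zeta)
        out = asdict(self)
        out["contract_version"] = CONTRACT_VERSION
        out["widths"] = list(pal.widths)
        out["alpha"] = list(pal.alpha)
        out["beta"] = list(pal.beta)
        out["n_colors"] = pal.n_colors
        if image_shape is not None and self.W is None:
            n = int(image_shape[0]) * int(image_shape[1])
            out["W"] = patch_halfwidth(n, self.P)
        return out

    def log_resolved(self, image_shape=None) -> dict:
        resolved = self.resolved(image_shape)
        log.info("resolved config: %s", json.dumps(resolved, sort_keys=True))
        return resolved
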