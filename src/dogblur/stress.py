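"""Seeded degradation stress suite for the blur metric.

Runs the full six-step pipeline over a reproducible grid of phantoms x
blur kinds x levels 0..15, plus two boundary inputs (a constant,
detail-free image and an undistorted sharp phantom), and collects the
per-image features and scores in one tidy DataFrame.  This is the batch
used to check the metric's standardized bounds, the initial-scale filter
identity, the edge-mean ordering, and blur monotonicity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .quality import MultiscaleConfig, assess_image
from .simulate import MAX_LEVEL, PhantomSpec, degradation_series, generate_phantom

__all__ = ["suite_phantom_specs", "run_stress_suite"]

#: default phantom grid: count, slice size, cycled region counts
N_PHANTOMS = 50
PHANTOM_SIZE = 128
REGION_COUNTS = (3, 4, 5, 6)


def suite_phantom_specs(seed: int, n_phantoms: int = N_PHANTOMS,
                        size: int = PHANTOM_SIZE) -> list[PhantomSpec]:
    """Phantom recipes for the suite; layouts alternate brain/cardiac."""
    child_seeds = np.random.SeedSequence(seed).generate_state(n_phantoms) % (2**31)
    return [
        PhantomSpec(
            d1=size,
            d2=size,
            n_regions=REGION_COUNTS[i % len(REGION_COUNTS)],
            seed=int(child_seeds[i]),
            layout="brain" if i % 2 == 0 else "cardiac",
        )
        for i in range(n_phantoms)
    ]


def run_stress_suite(
    seed: int = 0,
    n_phantoms: int = N_PHANTOMS,
    size: int = PHANTOM_SIZE,
    config: MultiscaleConfig | None = None,
) -> pd.DataFrame:
    """Score every suite image; one row per assessment.

    Columns: ``phantom`` (index, or -1 for the boundary inputs), ``kind``
    ("gaussian", "motion", "constant" or "ideal"), ``level``, the
    trajectory features ``mu_id``/``mu_ca``/``mu_cb`` and the first-scale
    means ``med1_1``/``med2_1``, the scores ``q1``/``q2``/``Q``, and the
    number of per-slice warnings.
    """
    config = config or MultiscaleConfig()
    rows: list[dict] = []

    def _record(phantom: int, kind: str, level: int, image: np.ndarray) -> None:
        res = assess_image(image, config)
        t = res.trajectory
        rows.append(
            {
                "phantom": phantom,
                "kind": kind,
                "level": level,
                "mu_id": t.mu_reference,
                "mu_ca": t.mu_ca,
                "mu_cb": t.mu_cb,
                "med1_1": t.mu_high[0],
                "med2_1": t.mu_low[0],
                "q1": res.score.q1,
                "q2": res.score.q2,
                "Q": res.score.Q,
                "n_warnings": len(res.warnings),
            }
        )

    specs = suite_phantom_specs(seed, n_phantoms, size)
    for i, spec in enumerate(specs):
        phantom = generate_phantom(spec)
        for kind in ("gaussian", "motion"):
            for level, degraded in degradation_series(phantom, kind):
                _record(i, kind, level, degraded)

    # boundary inputs: a detail-free constant image and a sharp phantom
    _record(-1, "constant", 0, np.full((size, size), 117.0))
    _record(-1, "ideal", 0, generate_phantom(specs[0]))

    df = pd.DataFrame(rows)
    assert len(df) == n_phantoms * 2 * (MAX_LEVEL + 1) + 2
    return df
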