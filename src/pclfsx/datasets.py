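"""Packaged example data."""

from __future__ import annotations

import json
from importlib import resources

import numpy as np

from .ranking import RankedFeatures
from .selection import GridScores

__all__ = ["load_demo_grid"]


def load_demo_grid() -> tuple[GridScores, int, float]:
    """The packaged 30-feature demonstration F1 grid.

    A synthetic fixture (not measured data): an idealised sequential-selection
    curve for a dataset with 10 informative features out of 30 — F1 climbs
    steeply while the informative features are added, then wanders on a noisy
    plateau with its global maximum at subset size 29. Running the
    gradient-threshold rule on it shows the characteristic contrast between
    the plain maximum selection (29 features) and the reduced selection
    (10 features).

    Returns
    -------
    grid : GridScores
    n_informative : int
    T : float
        The tolerance the demonstration uses.
    """
    payload = json.loads(
        resources.files("pclfsx").joinpath("data/demo_grid.json").read_text()
    )
    n = payload["n_features"]
    ranking = RankedFeatures(order=np.arange(n), scores=np.zeros(n))
    grid = GridScores(g=np.asarray(payload["g"], dtype=float), order_ref=ranking)
    return grid, int(payload["n_informative"]), float(payload["T"])
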