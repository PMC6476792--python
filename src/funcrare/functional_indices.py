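"""Species-level functional specialization, originality, and redundancy.

All three indices are read off a standardized trait space:

* specialization (FSpeS): Euclidean distance of a species to the community
  centroid (the origin of the z-scored space) — species far from the centroid
  hold extreme trait combinations;
* originality (FOriS): Euclidean distance to the nearest neighbouring
  species — large values mean the species is functionally isolated;
* redundancy (FRedS): the complement 1 − FOriS of the normalized
  originality — large values mean the trait combination is closely shared.

Raw distances in a k-axis z-scored space are unbounded, so the bounded
indices are obtained by dividing each raw index by its across-species
maximum (``normalize=True``, the default), giving a 0–1 scale on which the
most extreme species scores 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from .trait_space import FunctionalSpace


def specialization(space: FunctionalSpace, normalize: bool = True) -> np.ndarray:
    """Per-species distance to the centroid of the standardized space."""
    raw = np.linalg.norm(space.axes, axis=1)
    if not normalize:
        return raw
    m = raw.max()
    if m == 0:
        raise ValueError("all species coincide with the centroid; "
                         "normalized specialization undefined")
    return raw / m


def originality(space: FunctionalSpace, normalize: bool = True) -> np.ndarray:
    """Per-species Euclidean distance to its nearest neighbour."""
    if space.n_species < 2:
        raise ValueError("originality needs at least 2 species")
    d = squareform(pdist(space.axes, metric="euclidean"))
    np.fill_diagonal(d, np.inf)
    raw = d.min(axis=1)
    if not normalize:
        return raw
    m = raw.max()
    if m == 0:
        raise ValueError("all species are exact duplicates; "
                         "normalized originality undefined")
    return raw / m


def redundancy(fori: np.ndarray) -> np.ndarray:
    """FRedS = 1 − FOriS, defined on normalized originality in [0, 1]."""
    fori = np.asarray(fori, dtype=float)
    if np.any(fori < 0) or np.any(fori > 1):
        raise ValueError("redundancy expects normalized originality in [0, 1]")
    return 1.0 - fori


def compute_profiles(space: FunctionalSpace, normalize: bool = True) -> pd.DataFrame:
    """All three indices plus raw distances, one row per species.

    Columns: ``species, FSpeS, FOriS, FRedS, raw_centroid_dist, raw_nn_dist``.
    ``FRedS`` is reported only for normalized indices (NaN otherwise, since
    the complement is meaningful only on the 0–1 scale).
    """
    raw_spe = specialization(space, normalize=False)
    raw_ori = originality(space, normalize=False)
    fspes = specialization(space, normalize=True) if normalize else raw_spe
    foris = originality(space, normalize=True) if normalize else raw_ori
    freds = redundancy(foris) if normalize else np.full_like(foris, np.nan)
    return pd.DataFrame({
        "species": space.species,
        "FSpeS": fspes,
        "FOriS": foris,
        "FRedS": freds,
        "raw_centroid_dist": raw_spe,
        "raw_nn_dist": raw_ori,
    })
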