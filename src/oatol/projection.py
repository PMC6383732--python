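"""Single-generation selection-response projection (Lande equation).

The change in mean phenotype under selection is Δz = G β, where G is the
additive genetic (co)variance matrix and β the vector of selection
gradients.  Applied to larval mortality in two environments, the first
component is the direct response of the trait under selection (here,
mortality under present-day ambient conditions; a negative β favours
lower mortality) and the second is the correlated response of the same
trait expressed under acidified conditions — the "priming" of the
population for a future environment it has not yet experienced.
Projections are single-generation only: iterating them would require
assuming G stays constant across generations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .animal_model import PosteriorChain, PosteriorSummary, _summarize


def selection_response(G, beta) -> np.ndarray:
    """Per-generation change in trait means, Δz = G β."""
    G = np.asarray(G, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if G.ndim != 2 or G.shape[0] != G.shape[1]:
        raise ValueError("G must be square")
    if not np.allclose(G, G.T, atol=1e-10):
        raise ValueError("G must be symmetric")
    if beta.shape != (G.shape[0],):
        raise ValueError("beta length must match G dimension")
    if np.linalg.eigvalsh(G).min() < -1e-10:
        raise ValueError("G must be positive semidefinite")
    if not np.all(np.isfinite(beta)):
        raise ValueError("beta must be finite")
    return G @ beta


def posterior_response(
    chain: PosteriorChain, beta, interval: str = "hpd"
) -> list[PosteriorSummary]:
    """Posterior of Δz = G β over a chain, one summary per trait."""
    if len(chain) == 0:
        raise ValueError("empty chain")
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (len(chain.traits),):
        raise ValueError("beta length must match number of traits")
    dz = np.einsum("sij,j->si", chain.G, beta)
    return [
        _summarize(f"dz[{name}]", dz[:, t], interval) for t, name in enumerate(chain.traits)
    ]


def response_frame(summaries: list[PosteriorSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "trait": s.name[3:-1],
                "mean": s.mean,
                "median": s.median,
                "lower": s.lower,
                "upper": s.upper,
            }
            for s in summaries
        ]
    )
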