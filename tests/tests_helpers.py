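"""Shared helpers for constructing random test systems."""

import numpy as np

from chromosteer.polymer import SystemState


def scatter_state(rng, n=120, box=12.0, n_chains=3, min_pair=0.85):
    """Random multi-chain configuration grown bead by bead so that bonds
    stay in the safe FENE range and every pair distance (minimum image)
    is >= ``min_pair``.  Used as an oracle-friendly random input."""
    per = n // n_chains
    while True:
        placed = []
        ok = True
        for _ in range(n_chains):
            chain = _grow_chain(rng, per, box, placed, min_pair)
            if chain is None:
                ok = False
                break
            placed.extend(chain)
        if ok:
            pos = np.array(placed)
            starts = np.arange(0, n + 1, per)
            return SystemState(pos, starts, box)


def _grow_chain(rng, n, box, others, min_pair, max_retry=200):
    all_pts = list(others)
    chain = [rng.random(3) * box]
    all_pts.append(chain[0])
    for _ in range(n - 1):
        for attempt in range(max_retry):
            step = rng.normal(size=3)
            step *= rng.uniform(0.9, 1.1) / np.linalg.norm(step)
            cand = chain[-1] + step
            d = cand - np.asarray(all_pts)
            d -= box * np.round(d / box)
            if (np.sqrt((d ** 2).sum(1)) >= min_pair).all():
                chain.append(cand)
                all_pts.append(cand)
                break
        else:
            return None
    return chain
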