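"""Shared fixture builders for the chemistry tests."""

import numpy as np

from pulsechem import Ensemble


def pair_field(registry, n_pairs, r0, species="OH", delay=0.0, spacing=2e-6):
    """n isolated, well-separated pairs in one ensemble (mutually inert by
    distance), so a single engine call measures the pair reaction frequency."""
    idx = registry.species_index(species)
    side = int(np.ceil(np.sqrt(n_pairs)))
    ens = Ensemble(2 * n_pairs)
    for k in range(n_pairs):
        base = np.array([(k % side) * spacing, (k // side) * spacing, 1e-6])
        ens.add([idx], base, 0.0, k)
        ens.add([idx], base + [0.0, 0.0, r0], delay, k)
    return ens
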