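"""A minimal predictor plugin used by the CLI precompute test."""

import numpy as np


class _Harmonic:
    identifier = "example-harmonic"

    def evaluate(self, positions, atomic_numbers):
        energies = 0.5 * (positions**2).sum(axis=(1, 2))
        return energies, -positions


PREDICTOR = _Harmonic()
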