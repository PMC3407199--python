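"""Independent reference implementations used as test oracles."""

import numpy as np

from idpnmr import ClusterModelParams, PeptideSequence


def brute_force_r2(params: ClusterModelParams, seq: PeptideSequence):
    """Double-loop evaluation of the segmental-motion + cluster model,
    written without vectorization so it shares nothing with the
    implementation under test."""
    out = []
    for i in seq.indices:
        base = 0.0
        for pos, j in enumerate(seq.indices):
            base += params.weights[pos] * np.exp(
                -abs(float(i) - float(j)) / params.lambda0
            )
        total = params.a * base
        for comp in params.components:
            total += comp.r2c * np.exp(
                -((float(i) - comp.xc) ** 2) / (2 * comp.delta**2)
            )
        out.append(total)
    return np.array(out)
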