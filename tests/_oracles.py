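"""Independent reference implementations used to cross-check the FFT path."""

import numpy as np


def brute_force_scan(t: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Direct-sum linear correlation oracle: score(d) = sum t(v) p(v-d)."""
    nt, npr = np.array(t.shape), np.array(p.shape)
    out = np.zeros(tuple(nt + npr - 1))
    tp = np.pad(t, [(n - 1, n - 1) for n in npr])
    for dx in range(out.shape[0]):
        for dy in range(out.shape[1]):
            for dz in range(out.shape[2]):
                out[dx, dy, dz] = (
                    tp[dx:dx + npr[0], dy:dy + npr[1], dz:dz + npr[2]] * p
                ).sum()
    return out


def laplacian_stencil(a: np.ndarray) -> np.ndarray:
    """Independent 6-neighbor discrete Laplacian with zero boundary."""
    pad = np.pad(a, 1)
    return (
        pad[:-2, 1:-1, 1:-1] + pad[2:, 1:-1, 1:-1]
        + pad[1:-1, :-2, 1:-1] + pad[1:-1, 2:, 1:-1]
        + pad[1:-1, 1:-1, :-2] + pad[1:-1, 1:-1, 2:]
        - 6.0 * a
    )
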