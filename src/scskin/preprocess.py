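"""Normalization helpers shared by clustering, markers, DE and the classifier."""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .io import CountMatrix

__all__ = ["cp10k", "log_normalize"]


def cp10k(cm: CountMatrix) -> sp.csr_matrix:
    """Counts-per-10k depth normalization (columns scaled to 1e4 total)."""
    totals = np.asarray(cm.values.sum(axis=0)).ravel().astype(float)
    scale = np.divide(1e4, totals, out=np.zeros_like(totals), where=totals > 0)
    return cm.values.multiply(sp.csr_matrix(scale[None, :])).tocsr()


def log_normalize(cm: CountMatrix) -> sp.csr_matrix:
    """log1p of counts-per-10k; the default expression scale for statistics."""
    x = cp10k(cm)
    x.data = np.log1p(x.data)
    return x
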