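"""Pedigree-based additive (numerator) relationship matrix.

The A matrix is computed densely by the tabular (recursive) method over the
founders-first ordering of the pedigree:

    a(i, j) = 1/2 [a(j, s_i) + a(j, d_i)]   for j processed before i
    a(i, i) = 1 + 1/2 a(s_i, d_i)

with an unknown parent contributing 0.  The diagonal is 1 plus the
inbreeding coefficient.  Study-scale pedigrees (10^3-10^4 animals) fit
comfortably in dense memory, so no sparse-inverse machinery is used.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_formats import UNKNOWN_PARENT, PedigreeTable


def a_matrix(ped: PedigreeTable) -> tuple[np.ndarray, list[str]]:
    """Additive relationship matrix and its animal ordering (founders first)."""
    animals = ped.animals
    index = {a: i for i, a in enumerate(animals)}
    n = len(animals)
    A = np.zeros((n, n))
    sires = ped.df["sire"].tolist()
    dams = ped.df["dam"].tolist()
    for i in range(n):
        s = index.get(sires[i], -1) if sires[i] != UNKNOWN_PARENT else -1
        d = index.get(dams[i], -1) if dams[i] != UNKNOWN_PARENT else -1
        if s >= i or d >= i:
            raise ValueError("pedigree not in founders-first order")
        row = np.zeros(i)
        if s >= 0:
            row += A[s, :i]
        if d >= 0:
            row += A[d, :i]
        row *= 0.5
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return A, animals


def inbreeding(ped: PedigreeTable) -> pd.Series:
    A, animals = a_matrix(ped)
    return pd.Series(np.diag(A) - 1.0, index=animals, name="F")


def gene_drop_kinship(ped: PedigreeTable, n_drops: int, rng: np.random.Generator,
                      ) -> tuple[np.ndarray, list[str]]:
    """Monte-Carlo estimate of A by gene dropping.

    Two distinct founder alleles per founder are dropped through the
    pedigree ``n_drops`` times; the additive relationship is estimated as
    twice the average probability that a random allele from i and a random
    allele from j are identical by descent.  Independent check for
    :func:`a_matrix`, deliberately sharing no code with it.
    """
    animals = ped.animals
    index = {a: i for i, a in enumerate(animals)}
    n = len(animals)
    sires = [index.get(s, -1) if s != UNKNOWN_PARENT else -1 for s in ped.df["sire"]]
    dams = [index.get(d, -1) if d != UNKNOWN_PARENT else -1 for d in ped.df["dam"]]

    # allele labels per animal per replicate: (n, 2, n_drops) integer founder-allele ids
    labels = np.empty((n, 2, n_drops), dtype=np.int32)
    next_founder_allele = 0
    for i in range(n):
        for k, p in enumerate((sires[i], dams[i])):
            if p < 0:
                labels[i, k, :] = next_founder_allele
                next_founder_allele += 1
            else:
                pick = rng.integers(0, 2, size=n_drops)
                labels[i, k, :] = labels[p, pick, np.arange(n_drops)]

    K = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            ibd = np.zeros(n_drops)
            for a in range(2):
                for b in range(2):
                    ibd += labels[i, a, :] == labels[j, b, :]
            K[i, j] = K[j, i] = (ibd / 4.0).mean() * 2.0
    return K, animals
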