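"""Published reference inputs for the L. casei Zhang antibiotic-evolution study.

These are the printed measurements of the 2000-generation serial-passage
experiment on *Lactobacillus casei* Zhang: the MIC trajectories of the
gentamicin and amoxicillin arms (three replicate lineages each, read every
200 generations on a doubling-dilution series) and the reported per-arm
mean de novo mutation counts.  They serve as desk-scale inputs for the
fitness and rate analyses; everything else in this package is recomputed
from data.
"""

from __future__ import annotations

import numpy as np

from .io_formats import MicTable

#: Chromosome length of L. casei Zhang (bp); the rate denominator.
GENOME_LENGTH_BP = 2_861_848

#: Duration of the evolution experiment, in generations.
GENERATIONS_TOTAL = 2000

#: Reported mean number of de novo mutations per lineage after 2000
#: generations, by arm (A = amoxicillin, G = gentamicin, C = control).
REPORTED_MEAN_DENOVO = {"A": 19.0, "G": 21.5, "C": 5.5}

_GENERATIONS = [0, 200, 400, 600, 800, 1000, 1200, 1400, 1600, 1800, 2000]

_GENTAMICIN = [
    [2, 2, 2],
    [8, 8, 4],
    [8, 8, 8],
    [8, 8, 8],
    [16, 16, 16],
    [16, 16, 16],
    [32, 32, 32],
    [32, 32, 32],
    [32, 32, 32],
    [32, 32, 32],
    [32, 32, 32],
]

_AMOXICILLIN = [
    [2, 2, 2],
    [4, 4, 4],
    [4, 8, 4],
    [8, 8, 8],
    [8, 8, 8],
    [8, 8, 8],
    [8, 8, 8],
    [8, 8, 8],
    [8, 8, 8],
    [8, 8, 8],
    [8, 8, 8],
]


def gentamicin_mic() -> MicTable:
    """MIC grid (ug/mL) of the gentamicin arm, replicates G1-G3."""
    return MicTable(antibiotic="gentamicin", generations=list(_GENERATIONS),
                    replicate_ids=["G1", "G2", "G3"],
                    values=np.array(_GENTAMICIN, dtype=float))


def amoxicillin_mic() -> MicTable:
    """MIC grid (ug/mL) of the amoxicillin arm, replicates A1-A3.

    Replicate A2 steps to 8 ug/mL at generation 400 while A1/A3 follow at
    600 — the replicate disagreement the plateau rules must surface.
    """
    return MicTable(antibiotic="amoxicillin", generations=list(_GENERATIONS),
                    replicate_ids=["A1", "A2", "A3"],
                    values=np.array(_AMOXICILLIN, dtype=float))
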