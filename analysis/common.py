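"""Shared helpers for the analysis drivers: the study-scale dataset.

The study genome (24 chromosomes x 200 kb, ~2,000 planted SSRs, seed 42)
is regenerated deterministically on demand — generation takes about two
seconds, so nothing needs to be cached between scripts.
"""

from __future__ import annotations

import os

RESULTS = os.path.join(os.path.dirname(__file__), "..", "results")
SCRATCH = os.path.join(os.path.dirname(__file__), "..", "scratch")

STUDY_SEED = 42


def results_path(name: str) -> str:
    os.makedirs(RESULTS, exist_ok=True)
    return os.path.join(RESULTS, name)


def scratch_path(name: str) -> str:
    os.makedirs(SCRATCH, exist_ok=True)
    return os.path.join(SCRATCH, name)


def study_data():
    from ssrmine.synthetic_data import generate_genome, study_genome_spec

    spec = study_genome_spec(seed=STUDY_SEED)
    return spec, generate_genome(spec)
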