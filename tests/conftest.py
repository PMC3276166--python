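"""Shared fixtures: small references and the two session-scoped simulation
experiments reused across module and acceptance tests."""
from __future__ import annotations

import math

import numpy as np
import pytest

from iesmap import SimConfig, build_conmac, Contig
from iesmap.pipeline import PipelineConfig, run_simulation
from iesmap.simulate import evaluate_calls, expected_detectable


@pytest.fixture(scope="session")
def tiny_ref():
    """Two-contig reference for coordinate arithmetic (A:100, B:80)."""
    rng = np.random.default_rng(11)
    from iesmap._util import random_dna

    return build_conmac(
        [
            Contig("A", random_dna(rng, 100)),
            Contig("B", random_dna(rng, 80)),
        ]
    )


#: study conditions for the end-to-end error-free run: a 500 kb somatic
#: assembly with a mixed short/long IES complement at half junction coverage
E2E_CFG = SimConfig(
    seed=42,
    contig_lens=(300_000, 200_000),
    n_ies=60,
    short_fraction=0.5,
    coverage_fraction=0.5,
    error_rate=0.0,
    read_len_sd=0.0,
)


@pytest.fixture(scope="session")
def e2e():
    """Error-free end-to-end run: simulate -> align -> classify -> call."""
    genomes, sim, result = run_simulation(E2E_CFG)
    ev = evaluate_calls(result.sites, genomes.truth, result.ref)
    detectable = expected_detectable(genomes, sim, E2E_CFG)
    return {
        "cfg": E2E_CFG,
        "genomes": genomes,
        "sim": sim,
        "result": result,
        "eval": ev,
        "detectable": detectable,
    }


#: the coverage-law experiment: 200 read-spanning (long-class) IES per
#: replicate, ten replicates per coverage fraction
FLAW_SEEDS = range(10)
FLAW_FRACTIONS = (0.25, 0.5, 1.0)


def _flaw_cfg(seed: int, f: float) -> SimConfig:
    return SimConfig(
        seed=100 + seed,
        contig_lens=(500_000,),
        n_ies=200,
        short_fraction=0.0,
        coverage_fraction=f,
        error_rate=0.0,
        read_len_sd=0.0,
        min_ies_spacing=2000,
    )


@pytest.fixture(scope="session")
def coverage_law():
    """win1 detection as a function of junction coverage fraction f.

    Returns {f: list of (n_truth, n_win1_matched, n_win1_called)} pooled
    over seeds.
    """
    out: dict[float, list[tuple[int, int, int]]] = {}
    for f in FLAW_FRACTIONS:
        runs = []
        for seed in FLAW_SEEDS:
            genomes, _sim, result = run_simulation(_flaw_cfg(seed, f))
            ev = evaluate_calls(result.sites, genomes.truth, result.ref)
            n_win1 = sum(1 for s in result.sites if s.category == "win1")
            runs.append((len(genomes.truth), len(ev.matched_win1), n_win1))
        out[f] = runs
    return out


def binomial_sd(p: float, n: int) -> float:
    return math.sqrt(p * (1 - p) / n)
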