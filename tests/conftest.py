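import logging
import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle module

from meltdose import builtin_config, synthetic
from meltdose.models import CursorPair, MeltCurve
from meltdose.pcr import simulate_competitive_pcr

logging.getLogger("meltdose").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def grid():
    return synthetic.default_grid()


@pytest.fixture(scope="session")
def sma_config():
    return builtin_config("sma")


@pytest.fixture(scope="session")
def del22q_config():
    return builtin_config("del22q")


@pytest.fixture(scope="session")
def sma_reaction(sma_config):
    return sma_config.reaction("smn1_duplex")


def noiseless_curve(reaction, genotype, grid, background=(0.0, 0.1),
                    sample_id="s", tm_shift=0.0, gain=1.0):
    """Deterministic raw curve for a genotype (no noise)."""
    products = simulate_competitive_pcr(reaction, genotype)
    if background[0] == "auto":
        plateau = sum(products[a.name] * a.length for a in reaction.amplicons)
        background = (0.5 * plateau, background[1])
    return synthetic.synthesize_melt_curve(
        products, reaction.amplicons, grid, background=background,
        sample_id=sample_id, tm_shift=tm_shift, gain=gain,
    )


@pytest.fixture(scope="session")
def sma_cursors():
    # default cursors for the SMN1 duplex on the standard grid
    return CursorPair(68.5, 82.5)
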