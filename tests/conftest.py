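import math

import numpy as np
import pytest

from mctkit.datamodel import GrowthCurve, MCTDataset


def make_curve(volumes, days=None, mouse_id="m1", model_id="P1", arm="treatment"):
    """Build a GrowthCurve from a volume list (days default 0,7,14,...)."""
    if days is None:
        days = tuple(7 * i for i in range(len(volumes)))
    return GrowthCurve(
        mouse_id=mouse_id, model_id=model_id, arm=arm, days=tuple(days),
        volumes=tuple(volumes),
    )


def rtv_curve(rtvs, days=None, baseline=100.0, **kw):
    """Curve whose RTV series at the measured days equals ``rtvs``."""
    return make_curve([baseline * r for r in rtvs], days=days, **kw)


def exp_curve(k, days, tv0=100.0, **kw):
    """Noise-free exponential curve TV_0 * exp(k d)."""
    return make_curve([tv0 * math.exp(k * d) for d in days], days=days, **kw)


def make_dataset(curves, expression=None):
    covs = {c.model_id: {"cancer_type": "NA"} for c in curves}
    return MCTDataset(curves=list(curves), model_covariates=covs, expression=expression)


@pytest.fixture
def toy_dataset():
    """Two models x two arms x two mice, clean exponential growth."""
    curves = []
    days = (0, 7, 14, 21)
    for model, kv, kt in (("P1", 0.08, 0.03), ("P2", 0.06, 0.02)):
        for i in range(2):
            curves.append(
                exp_curve(kv, days, tv0=120 + 10 * i, mouse_id=f"{model}v{i}",
                          model_id=model, arm="vehicle")
            )
            curves.append(
                exp_curve(kt, days, tv0=120 + 10 * i, mouse_id=f"{model}t{i}",
                          model_id=model, arm="treatment")
            )
    return make_dataset(curves)
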