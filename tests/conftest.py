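import math
import warnings

import numpy as np
import pytest

from lrfit import FitPlan, LongRangeModel, MoleculeSpec, SystemSpec
from lrfit.expansion import Expansion
from lrfit.fitting import _Parametrization, default_stages, gauge_align
from lrfit.synthetic import SyntheticModel, random_coefficients, synthetic_dataset


def stages_capped(sys, caps):
    """Order-by-order stages clamped to per-interaction caps."""
    stages = default_stages(sys, max(caps.values()))
    out = []
    for st in stages:
        st2 = {k: min(v, caps[k]) for k, v in st.items() if caps.get(k, 0) > 0}
        if st2 and (not out or st2 != out[-1]):
            out.append(st2)
    return out


def run_recovery(sys, caps, seed, n_mult=8, noise_sigma=0.0, fixed=None):
    """Fit a synthetic dataset of the given system; return (result, truth,
    model, per-parameter relative errors after gauge alignment)."""
    truth = random_coefficients(sys, caps, seed=seed)
    synth = SyntheticModel(sys, truth, caps, seed)
    exp = Expansion(sys, caps)
    plan = FitPlan(stages=stages_capped(sys, caps), seed=seed, fixed=fixed or {})
    par = _Parametrization(exp, plan)
    data = synthetic_dataset(synth, n_mult * max(par.n_free, 3), noise_sigma=noise_sigma)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = LongRangeModel(data, sys, plan)
        res = model.fit()
    est = gauge_align(model.expansion, res.coefficients, truth, plan)
    errs = []
    for key in model.expansion.parameter_keys:
        tv = model.expansion.get_entry(truth, key)
        ev = model.expansion.get_entry(est, key)
        if abs(tv) > 1e-12:
            errs.append(abs(ev - tv) / abs(tv))
    return res, truth, model, np.array(errs)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def mol(pg, charge=0.0, sites=None, name=None):
    return MoleculeSpec(name or pg, pg, charge=charge, sites=sites)
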