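"""Shared fixtures.

Heavy artifacts (registered cohort, trained generators, the reduced
benchmark) are session-scoped and shared between the unit tests and the
acceptance tests so expensive models are trained once per session.
"""

from __future__ import annotations

import numpy as np
import pytest

from craniosynth import classify, distmap, headgen, registration

COHORT_SEED = 20240

# scaled-down study conditions used by the in-suite benchmark analog: full
# 496-head cohort, one fold, reduced per-source sample counts; the GAN epoch
# count targets the desk-scale optimization budget (~2400 critic steps on the
# 372 model-data images)
BENCH_N_PER_CLASS = 100
BENCH_CNN_EPOCHS = 30
BENCH_GAN_EPOCHS = 220


@pytest.fixture(scope="session")
def small_heads():
    """A handful of heads per class for cheap geometric tests."""
    return {
        label: [headgen.synth_head(label, 100 + s) for s in range(8)]
        for label in headgen.CLASSES
    }


@pytest.fixture(scope="session")
def template():
    return registration.build_template(n=10, seed=9)


@pytest.fixture(scope="session")
def fixture_cohort():
    return headgen.synth_cohort(headgen.CohortSpec(seed=COHORT_SEED))


@pytest.fixture(scope="session")
def corresponded(fixture_cohort, template):
    return registration.register_cohort(fixture_cohort, template)


@pytest.fixture(scope="session")
def clinical_maps(fixture_cohort):
    return {h.subject_id: distmap.encode_distance_map(h) for h in fixture_cohort}


@pytest.fixture(scope="session")
def class_maps(clinical_maps, fixture_cohort):
    out = {label: [] for label in headgen.CLASSES}
    for h in fixture_cohort:
        out[h.label].append(clinical_maps[h.subject_id])
    return out


@pytest.fixture(scope="session")
def benchmark_report(fixture_cohort, corresponded, clinical_maps):
    """One-fold benchmark analog (shared by the GAN conditioning test, the
    similarity tests and the acceptance tests)."""
    cfg = classify.BenchmarkConfig(
        k=4,
        folds=(0,),
        n_per_class=BENCH_N_PER_CLASS,
        gan_epochs=BENCH_GAN_EPOCHS,
        train=classify.TrainConfig(epochs=BENCH_CNN_EPOCHS),
        seed=7,
    )
    return classify.run_benchmark(fixture_cohort, corresponded, clinical_maps, cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
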