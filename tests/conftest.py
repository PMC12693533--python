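"""Shared fixtures: synthetic scenes and pipeline runs reused across tests."""

from __future__ import annotations

import pytest

from episplice import pipeline
from episplice.classify_interpret import ClassifierConfig
from episplice.synthetic_data import SceneConfig, generate_scene


#: compact scene for unit-level checks (smaller gene classes, same structure)
SMALL_CONFIG = SceneConfig(
    seed=11,
    n_genes=140,
    n_epi_per_mark=4,
    n_nonepi=20,
    n_distractor_per_flavor=3,
    n_mxe=2,
    n_constitutive_dhm=6,
    n_low_tsl=6,
    n_tss_leak=2,
    n_eclip_background=400,
    n_bg_peaks_per_mark=10,
)


@pytest.fixture(scope="session")
def small_scene():
    return generate_scene(SMALL_CONFIG)


@pytest.fixture(scope="session")
def default_scene():
    """The default study-condition scene (300 genes, 5 marks, 160 RBPs)."""
    return generate_scene(SceneConfig())


@pytest.fixture(scope="session")
def default_scene_dir(default_scene, tmp_path_factory):
    return default_scene.write(tmp_path_factory.mktemp("scene"))


@pytest.fixture(scope="session")
def default_pipeline(default_scene, default_scene_dir):
    """Annotation bundle plus per-comparison caller results on the default scene."""
    bundle = pipeline.prepare_annotation(default_scene_dir / "annotation.gff3")
    results = []
    for i in range(len(default_scene.config.comparisons)):
        comp = default_scene_dir / default_scene.comparison_name(i)
        deu = [comp / "SE.MATS.JC.txt"]
        mxe = comp / "MXE.MATS.JC.txt"
        if mxe.exists():
            deu.append(mxe)
        dhm = {m: comp / f"dhm_{m}.tsv" for m in default_scene.config.marks}
        results.append(pipeline.run_comparison(bundle, deu, dhm))
    return bundle, results


@pytest.fixture(scope="session")
def focus_classification(default_scene):
    """Classifier + attribution on the focus mark of the default scene."""
    from episplice.synthetic_data import binding_events_from_hits

    scene = default_scene
    events = binding_events_from_hits(scene.binding_hits)
    epi = set(scene.truth.epi_flanks[scene.config.focus_mark])
    ctrl = set(scene.truth.control_flanks)
    return pipeline.classify_mark(
        events,
        epi,
        ctrl,
        mark=scene.config.focus_mark,
        config=ClassifierConfig(repeats=3, seed=7),
    )
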