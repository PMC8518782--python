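import json

import pytest

from markergenie.pipeline import run_synthetic_study
from markergenie.synthdata import demo_dataset


@pytest.fixture(scope="session")
def demo_ds():
    """The canonical demo study: 3 samples, 6 genes, 2 decoy families."""
    return demo_dataset(seed=42)


@pytest.fixture(scope="session")
def demo_run(demo_ds):
    """Full pipeline run on the demo study (build + calibrate + scan)."""
    result, hmms, registry = run_synthetic_study(demo_ds)
    return {"result": result, "hmms": hmms, "registry": registry}


#: a miniature plan used by CLI tests to keep them fast
TINY_PLAN = {
    "families": {
        "katG": {"root_length": 60, "n_members": 56},
        "sodA": {"root_length": 60, "n_members": 56},
        "katG_paralog": {
            "root_length": 60, "n_members": 56,
            "anchor_family": "katG", "shared_fraction": 0.4,
        },
    },
    "gene_categories": {"katG": "catalase", "sodA": "superoxide_dismutase"},
    "decoy_families": ["katG_paralog"],
    "samples": [
        {
            "sample_id": "S1_5", "site": "S1", "depth_mbsf": 5.0,
            "sulfate_status": "present",
            "plants": [["katG", "Proteobacteria", 2], ["sodA", "Firmicutes", 1]],
            "n_decoy_orfs": 2, "n_random_contigs": 5,
        },
        {
            "sample_id": "S2_40", "site": "S2", "depth_mbsf": 40.0,
            "sulfate_status": "depleted",
            "plants": [["sodA", "Chloroflexi", 2]],
            "n_decoy_orfs": 2, "n_random_contigs": 5,
        },
    ],
}


@pytest.fixture()
def tiny_plan_file(tmp_path):
    p = tmp_path / "plan.json"
    p.write_text(json.dumps(TINY_PLAN))
    return p
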