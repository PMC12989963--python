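import pandas as pd
import pytest

import aquarisk as aq


@pytest.fixture(scope="session")
def config():
    return aq.StudyConfig(seed=1)


@pytest.fixture(scope="session")
def small_dataset():
    """Compact synthetic dataset: 5 provinces, 4 antibiotics, 4 years."""
    truth = aq.make_ground_truth(5, 4, seed=11)
    return aq.generate_dataset(truth, 400, (2015, 2018))


@pytest.fixture(scope="session")
def small_pipeline(small_dataset, config):
    ds = small_dataset
    cfg = config.replace(year_range=(2015, 2018))
    budgets = {j: 200 for j in ds.truth.provinces}
    baseline = aq.baseline_allocation(ds.truth, 200)
    return aq.run_pipeline(ds.records, ds.trade, ds.consumption, ds.reference,
                           cfg, budgets=budgets, baseline_alloc=baseline)


@pytest.fixture(scope="session")
def preset_dataset():
    """Study-scale preset: 31 provinces, 2015-2022, ~300k samples."""
    return aq.paper_scale_preset(seed=42)


@pytest.fixture(scope="session")
def preset_pipeline(preset_dataset):
    ds = preset_dataset
    cfg = aq.StudyConfig(seed=42)
    budgets = {j: 1200 for j in ds.truth.provinces}
    baseline = aq.baseline_allocation(ds.truth, 1200)
    return aq.run_pipeline(ds.records, ds.trade, ds.consumption, ds.reference,
                           cfg, budgets=budgets, baseline_alloc=baseline)


@pytest.fixture()
def tiny_records_csv(tmp_path):
    """Hand-written 4-sample long-format CSV (one multi-hazard failure)."""
    rows = [
        # sample_id, year, monitor, source, category, result, hazard, class, conc, limit
        ("S1", 2016, "ZJ", "ZJ", "fish", "pass", "", "", "", ""),
        ("S2", 2016, "ZJ", "JS", "fish", "fail", "Enrofloxacin", "antibiotic", 250.0, 100.0),
        ("S2", 2016, "ZJ", "JS", "fish", "fail", "Chloramphenicol", "antibiotic", 4.0, 0.0),
        ("S3", 2017, "ZJ", "", "shrimp", "fail", "Cadmium", "other", 180.0, 100.0),
        ("S4", 2017, "JS", "JS", "fish", "pass", "", "", "", ""),
    ]
    df = pd.DataFrame(rows, columns=aq.io.SAMPLING_COLUMNS)
    path = tmp_path / "sampling_records.csv"
    df.to_csv(path, index=False)
    return path
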