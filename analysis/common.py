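"""Shared paths and loaders for the numbered analysis scripts."""

from pathlib import Path

from wireworm.data import Species, complete_case_pairs, read_dataset

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
DATASETS = RESULTS / "datasets"
SEED = 20260901


def load_pairs(species: Species):
    """Complete-case pairs for one species from the simulated datasets."""
    ds = read_dataset(DATASETS / f"{species.value}.csv")
    return complete_case_pairs(ds, species)
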