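import numpy as np
import pytest

from pestaug import ImageRecord, LabeledDataset


def make_record(seed: int = 0, h: int = 24, w: int = 24,
                label: str = "AJ", source_id: str | None = None) -> ImageRecord:
    rng = np.random.default_rng(seed)
    px = rng.integers(0, 256, size=(h, w, 3), dtype=np.uint8)
    return ImageRecord(px, label, source_id or f"{label}/img_{seed}")


@pytest.fixture
def record():
    return make_record(0)


@pytest.fixture
def small_dataset():
    recs = [make_record(i, label=lab, source_id=f"{lab}/img_{i}")
            for i, lab in enumerate(["AJ"] * 4 + ["TR"] * 3)]
    return LabeledDataset(recs, ["AJ", "TR"])


def separable_two_class(n_per: int, seed: int = 7,
                        side: int = 48) -> LabeledDataset:
    """Two classes separated by a large constant color offset plus pixel noise."""
    rng = np.random.default_rng(seed)
    recs = []
    for cls, base in [("A", (200, 40, 40)), ("B", (40, 40, 200))]:
        for i in range(n_per):
            px = np.clip(rng.normal(base, 15.0, size=(side, side, 3)),
                         0, 255).astype(np.uint8)
            recs.append(ImageRecord(px, cls, f"{cls}/{i}"))
    return LabeledDataset(recs, ["A", "B"])
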