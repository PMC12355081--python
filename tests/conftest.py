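import numpy as np
import pandas as pd
import pytest

from parpomics.io_design import SampleDesign


@pytest.fixture
def design_2x2() -> SampleDesign:
    """Two cell lines x one treatment x 4 replicates."""
    samples = [f"{ln}.r{r}" for ln in ("parent", "ORA") for r in range(1, 5)]
    return SampleDesign(
        samples=tuple(samples),
        line={s: s.split(".")[0] for s in samples},
        treatment={s: "untreated" for s in samples},
        replicate={s: int(s.rsplit("r", 1)[1]) for s in samples},
    )


@pytest.fixture
def design_full() -> SampleDesign:
    from parpomics.synthetic import default_design

    return default_design()


def random_evidence(rng: np.random.Generator, n_records: int) -> pd.DataFrame:
    """Small random evidence table exercising every filtering rule."""
    n_sites = max(1, n_records // 3)
    sites = [(f"P{i}", int(rng.integers(1, 50)), str(rng.choice(list("SRY"))))
             for i in range(n_sites)]
    rows = []
    for _ in range(n_records):
        prot, pos, res = sites[int(rng.integers(n_sites))]
        rows.append(
            {
                "peptide": "PEPTIDEK",
                "protein": prot,
                "position": pos,
                "residue": res,
                "n_ptm": int(rng.choice([0, 1, 1, 1, 2])),
                "localization_prob": float(rng.choice(
                    [0.3, 0.5, 0.75, 0.76, 0.9, 0.91, 0.95, 1.0])),
                "sample": str(rng.choice(["parent.r1", "parent.r2", "parent.r3",
                                          "parent.r4", "ORA.r1", "ORA.r2",
                                          "ORA.r3", "ORA.r4"])),
                "intensity": float(rng.uniform(10, 1e6))
                if rng.random() > 0.15 else np.nan,
                "is_reverse": bool(rng.random() < 0.1),
                "is_contaminant": bool(rng.random() < 0.1),
            }
        )
    return pd.DataFrame(rows)
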