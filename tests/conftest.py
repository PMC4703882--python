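import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from fascreen.family import FamilyGenotypes, Pedigree

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

QUAD = Pedigree(father_id="F", mother_id="M", index_id="P", sibling_id="S")

_GT = {
    "0/0": (0, 0), "0/1": (0, 1), "1/0": (1, 0), "1/1": (1, 1),
    "./.": (-1, -1), "./0": (-1, 0), "0/.": (0, -1),
    "./1": (-1, 1), "1/.": (1, -1),
}


def make_fg(rows, ped=QUAD):
    """Build a small FamilyGenotypes from dict rows.

    Each row: chrom, pos, ref, alt plus optional gene/consequence/
    splice_offset/freq_*/pred_* columns, a ``gt`` dict sample -> "0/1"-style
    genotype string, and an optional ``lowq`` list of samples whose call is
    LOW quality.
    """
    var_rows, calls, quality = [], [], []
    for r in rows:
        var = {k: v for k, v in r.items() if k not in ("gt", "lowq")}
        var.setdefault("vclass", "SNV")
        var.setdefault("gene", "")
        var.setdefault("consequence", "")
        var_rows.append(var)
        calls.append([_GT[r["gt"].get(s, "0/0")] for s in ped.samples])
        lowq = r.get("lowq", [])
        quality.append([s not in lowq for s in ped.samples])
    variants = pd.DataFrame(var_rows)
    return FamilyGenotypes(
        ped,
        variants,
        np.array(calls, dtype=np.int8),
        np.array(quality, dtype=bool),
    )


@pytest.fixture
def quad_ped():
    return QUAD
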