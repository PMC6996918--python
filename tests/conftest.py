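import pandas as pd
import pytest

from aselof import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_bundle():
    """A small paired cohort shared by read-only tests."""
    return simulate_cohort(SimConfig(n_patients=4, n_genes=20, seed=3))


@pytest.fixture(scope="session")
def bundle_dir(small_bundle, tmp_path_factory):
    """The same cohort written to disk in its interchange formats."""
    d = tmp_path_factory.mktemp("bundle")
    paths = small_bundle.write_dir(d)
    return paths


def make_counts(rows, sample="S1", assay="RNA"):
    """Build an allele-count table from (ref, alt) or full dict rows."""
    out = []
    for i, row in enumerate(rows):
        if isinstance(row, dict):
            base = row
        else:
            ref, alt = row
            base = {"refCount": ref, "altCount": alt}
        rec = {
            "contig": "chr1",
            "position": 1000 + 100 * i,
            "variantID": f"s{i + 1}",
            "refAllele": "A",
            "altAllele": "G",
            "sample": sample,
            "assay": assay,
        }
        rec.update(base)
        rec.setdefault("totalCount", rec["refCount"] + rec["altCount"])
        out.append(rec)
    return pd.DataFrame(out)
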