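import numpy as np
import pandas as pd
import pytest

from deltaprot.io import ProteinQuantTable, SampleManifest


def build_manifest(n_patients: int) -> SampleManifest:
    patients = [f"PT{i + 1:03d}" for i in range(n_patients)]
    return SampleManifest(
        pd.DataFrame(
            {
                "patient_id": patients * 2,
                "sample_id": [f"{p}-BL" for p in patients] + [f"{p}-FU" for p in patients],
                "timepoint": ["baseline"] * n_patients + ["followup"] * n_patients,
            }
        )
    )


def build_table(
    intensities: pd.DataFrame,
    reverse=(),
    contaminant=(),
    only_site=(),
) -> ProteinQuantTable:
    """Protein table from an accession-indexed intensity frame (NaN = missing)."""
    meta = pd.DataFrame(
        {
            "gene_name": [f"G{i}" for i in range(len(intensities))],
            "unique_peptides": 2,
            "reverse": [a in set(reverse) for a in intensities.index],
            "contaminant": [a in set(contaminant) for a in intensities.index],
            "only_identified_by_site": [a in set(only_site) for a in intensities.index],
        },
        index=intensities.index.rename("accession"),
    )
    return ProteinQuantTable(meta, intensities.astype(float))


def random_table(rng: np.random.Generator, n_proteins: int, manifest: SampleManifest,
                 missing_rate: float = 0.1) -> ProteinQuantTable:
    sids = manifest.sample_ids
    vals = 2.0 ** rng.normal(25, 2, size=(n_proteins, len(sids)))
    mask = rng.random(vals.shape) < missing_rate
    vals[mask] = np.nan
    idx = pd.Index([f"SP{i:04d}" for i in range(n_proteins)], name="accession")
    return build_table(pd.DataFrame(vals, index=idx, columns=sids))


@pytest.fixture
def manifest3() -> SampleManifest:
    return build_manifest(3)


@pytest.fixture
def manifest6() -> SampleManifest:
    return build_manifest(6)
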