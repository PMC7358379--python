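"""Shared fixtures: synthetic datasets at the study's default scale,
generated once per session, plus small hand-built objects."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from plexquant import differential_table, merge_common, preset, relative_abundance
from plexquant.simulate import write_fixture_set

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def paper_data():
    """Default two-plex study-shaped dataset with ground truth."""
    truth, tables, designs = preset("paper")
    return truth, tables, designs


@pytest.fixture(scope="session")
def paper_merged(paper_data):
    truth, tables, designs = paper_data
    mats = [relative_abundance(t, d) for t, d in zip(tables, designs)]
    return merge_common(mats)


@pytest.fixture(scope="session")
def paper_diff(paper_merged, paper_data):
    truth, _, _ = paper_data
    return differential_table(paper_merged, truth.control)


@pytest.fixture(scope="session")
def paper_fixture_dir(paper_data, tmp_path_factory):
    """The default dataset written to disk as a parseable fixture set."""
    truth, tables, designs = paper_data
    out = tmp_path_factory.mktemp("paper_fixture")
    paths = write_fixture_set(truth, tables, designs, out)
    return paths


@pytest.fixture(scope="session")
def minimal_fixture_dir(tmp_path_factory):
    truth, tables, designs = preset("minimal")
    out = tmp_path_factory.mktemp("minimal_fixture")
    paths = write_fixture_set(truth, tables, designs, out)
    return truth, paths


def make_matrix(values: dict, groups: dict, ref_ratios: dict | None = None):
    """Hand-build a RelativeAbundanceMatrix from plain dicts.

    ``values``: accession -> list of ratios (one per sample);
    ``groups``: sample_id -> (plex_id, group, replicate).
    """
    from plexquant.quantify import RelativeAbundanceMatrix

    sample_ids = list(groups)
    vals = pd.DataFrame.from_dict(values, orient="index", columns=sample_ids)
    vals.index.name = "accession"
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "plex_id": [groups[s][0] for s in sample_ids],
            "group": [groups[s][1] for s in sample_ids],
            "replicate": [groups[s][2] for s in sample_ids],
        }
    )
    ref = pd.DataFrame(ref_ratios or {}, index=vals.index)
    return RelativeAbundanceMatrix(
        values=vals,
        samples=samples,
        reference_ratios=ref,
        annotations=pd.DataFrame(index=vals.index),
        n_detected=len(vals),
    )
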