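"""Shared fixtures: fixture marker sets, small and large synthetic communities.

Communities and detection runs are session-scoped — they are deterministic
given their seeds and several test modules share them.
"""

from __future__ import annotations

import pytest

from uscg.detect import build_profile, collect_marker_sequences, detect_copies
from uscg.marker_sets import builtin_cog_annotations, builtin_marker_sets
from uscg.synthetic_data import CommunitySpec, generate_community


@pytest.fixture(scope="session")
def builtin_sets():
    return builtin_marker_sets()


@pytest.fixture(scope="session")
def annotations():
    return builtin_cog_annotations()


@pytest.fixture(scope="session")
def default_community():
    """Default study conditions: 3 genera x 3 species x 2 strains, 40 markers,
    species pairs ~10% diverged, strain pairs ~0.2%, no dup/loss."""
    return generate_community(CommunitySpec(seed=7))


@pytest.fixture(scope="session")
def default_profiles(default_community):
    return [build_profile(rows, cog, pseudocount_weight=1.0)
            for cog, rows in sorted(default_community.seed_msas.items())]


@pytest.fixture(scope="session")
def default_detection(default_community, default_profiles):
    hits, matrix = detect_copies(default_community.proteomes, default_profiles)
    return hits, matrix


@pytest.fixture(scope="session")
def default_marker_sequences(default_community, default_detection):
    hits, _ = default_detection
    return collect_marker_sequences(hits, default_community.proteomes)


@pytest.fixture(scope="session")
def lossy_community_500():
    """40 markers x 500 genomes with 1% marker loss (mean 39.6 present/genome)."""
    return generate_community(CommunitySpec(
        seed=11, n_genera=25, species_per_genus=5, strains_per_species=4,
        loss_rate=0.01))


@pytest.fixture(scope="session")
def lossy_detection_500(lossy_community_500):
    com = lossy_community_500
    profiles = [build_profile(rows, cog) for cog, rows in sorted(com.seed_msas.items())]
    return detect_copies(com.proteomes, profiles)
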