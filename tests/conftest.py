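import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cognet.connectivity import ConnectivityMatrix

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def tiny_parcellation(n_gm_regions: int = 2) -> dict:
    """Small bilateral parcellation: n GM regions + thalamus + WM + CSF."""
    regions = {}
    lab = 1
    for i in range(n_gm_regions):
        regions[f"region_{chr(97 + i)}"] = {
            "labels": {"L": lab, "R": lab + 1}, "tissue": "GM", "weight": 1.0,
        }
        lab += 2
    for name, tissue, w in [("thalamus", "GM", 1.0), ("white", "WM", 2.0),
                            ("csf", "CSF", 1.0)]:
        regions[name] = {"labels": {"L": lab, "R": lab + 1},
                         "tissue": tissue, "weight": w}
        lab += 2
    return regions


@pytest.fixture
def small_sim_config():
    """Fast simulation config over a reduced parcellation.

    base_connectivity/weakened_links are explicit because the packaged
    network defaults do not resolve against the reduced parcellation.
    """
    from cognet.synthetic import SimulationConfig

    return SimulationConfig(
        n_controls=4,
        n_patients=2,
        n_timepoints=60,
        grid_shape=(10, 10, 8),
        total_labeled_voxels=500,
        parcellation=tiny_parcellation(),
        base_connectivity={("region_a_L", "region_a_R"): 0.6},
        weakened_links={},
        seed=123,
    )


def matrix_from_links(
    values, node_order, subject_id="s0", network="net"
) -> ConnectivityMatrix:
    """Symmetric unit-diagonal matrix from upper-triangle link values."""
    n = len(node_order)
    r = np.eye(n)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            r[i, j] = r[j, i] = values[k]
            k += 1
    assert k == len(values)
    return ConnectivityMatrix(
        subject_id=subject_id, network_name=network, r=r,
        node_order=tuple(node_order),
    )


@pytest.fixture
def link_matrix_factory():
    return matrix_from_links
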