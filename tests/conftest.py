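import pytest

from sceqtl.cross import (
    ArchitectureSpec,
    GeneticMap,
    ObservationParams,
    plant_architecture,
    simulate_cells,
    simulate_cross,
)


@pytest.fixture(scope="session")
def small_map() -> GeneticMap:
    return GeneticMap.regular(2, 50, 500, 1.0)


@pytest.fixture(scope="session")
def small_panel(small_map):
    return simulate_cross(small_map, 60, 11)


@pytest.fixture(scope="session")
def small_world(small_panel):
    """Panel + planted architecture + observed cells, one coherent universe."""
    spec = ArchitectureSpec(n_genes=40, n_qtl=4, n_hotspots=1)
    arch, fitness, expr_mean = plant_architecture(small_panel, spec, 21)
    obs = ObservationParams(
        breadth=0.4, error_rate=0.02, swap_rate=0.02, mean_cells_per_strain=3.0
    )
    counts, umi, truth = simulate_cells(small_panel, expr_mean, obs, 31)
    return {
        "panel": small_panel,
        "arch": arch,
        "fitness": fitness,
        "expr_mean": expr_mean,
        "obs": obs,
        "counts": counts,
        "umi": umi,
        "truth": truth,
    }
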