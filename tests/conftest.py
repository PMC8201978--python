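import numpy as np
import pandas as pd
import pytest

import aquadust as aq


@pytest.fixture(scope="session")
def ref_model() -> aq.GelFretModel:
    """Calibrated reporter model used as generating truth throughout."""
    return aq.GelFretModel.reference()


@pytest.fixture(scope="session")
def recipe() -> aq.SpectrumRecipe:
    return aq.SpectrumRecipe()


@pytest.fixture(scope="session")
def bands() -> aq.SpectralBands:
    return aq.SpectralBands()


@pytest.fixture(scope="session")
def background(recipe) -> aq.EmissionSpectrum:
    return aq.make_autofluorescence(recipe)


@pytest.fixture(scope="session")
def segmentation() -> aq.LeafSegmentation:
    return aq.LeafSegmentation()


@pytest.fixture(scope="session")
def xylem_curve() -> aq.VulnerabilityCurve:
    return aq.literature_xylem_curve()


@pytest.fixture(scope="session")
def ox_curve() -> aq.VulnerabilityCurve:
    """Outside-xylem curve at the reported fitted values."""
    return aq.VulnerabilityCurve(r_sat=3.7e3, psi50=-0.45)


def make_gradient_frame(noise_sd: float, seed: int, *, xylem_only_truth: bool = False,
                        psi_base: dict | None = None) -> pd.DataFrame:
    """Synthetic gradient dataset from the default scenario truth."""
    kwargs = {"noise_sd": noise_sd, "seed": seed}
    if psi_base is not None:
        kwargs["psi_base"] = psi_base
    truth = aq.ScenarioTruth(**kwargs)
    if xylem_only_truth:
        # data generated by a xylem-limited leaf: no outside-xylem resistor
        seg = aq.LeafSegmentation()
        rng = np.random.default_rng(seed)
        rows = []
        for (cond, day), pb in sorted(truth.psi_base.items(), key=lambda kv: str(kv[0])):
            st = aq.solve_steady_state(truth.e_rate, pb, seg, truth.v_xyl, None)
            for si, name in enumerate(seg.site_names):
                for plant in range(truth.n_plants):
                    for _ in range(truth.n_measurements):
                        noise = rng.normal(0, noise_sd) if noise_sd > 0 else 0.0
                        rows.append((f"P{plant+1}", cond, day, name,
                                     min(st.psi_xyl[si] + noise, 0.0)))
        return pd.DataFrame(rows, columns=["plant_id", "condition", "day",
                                           "position", "psi_mpa"])
    return aq.make_gradient_dataset(truth)
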