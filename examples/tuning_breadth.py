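"""Tuning-breadth statistics: lifetime kurtosis and sparseness.

Builds one narrowly tuned and one broadly tuned synthetic unit and shows
how lifetime kurtosis (LTK) separates them, plus the odorant-wise view
(population kurtosis) and the bell-shaped tuning-curve arrangement.
"""

import pandas as pd

import odorfusion as of

narrow = of.simulate_ground_truth(
    of.SimulationConfig(n_odorants=80, tuning_shape="one-hot", seed=1)
)
broad = of.simulate_ground_truth(
    of.SimulationConfig(n_odorants=80, tuning_shape="uniform", seed=2)
)
broad2 = of.simulate_ground_truth(
    of.SimulationConfig(n_odorants=80, tuning_shape="uniform", seed=3)
)
skewed = of.simulate_ground_truth(
    of.SimulationConfig(n_odorants=80, tuning_shape="exponential", seed=4)
)

matrix = of.ResponseMatrix(
    values=pd.DataFrame(
        {"narrow-unit": narrow, "broad-unit": broad,
         "broad-unit-2": broad2, "skewed-unit": skewed}
    ),
    scale_state="sfr-reset",
)

table = of.rank_profiles_by_ltk(matrix, min_n=50)
print("LTK ranking (high = narrow tuning, 0 = Gaussian, negative = broad):")
print(table.to_string(index=False))

for unit in matrix.units:
    lts, _ = of.lifetime_sparseness(matrix.column(unit))
    print(f"lifetime sparseness of {unit}: {lts:.3f} (1 = one ligand only)")

# odorant-wise view: a private ligand across a 12-unit population
import numpy as np

rng = np.random.default_rng(9)
population = pd.DataFrame(
    rng.uniform(0, 0.25, size=(80, 12)),
    index=narrow.index,
    columns=[f"unit{i:02d}" for i in range(12)],
)
population.loc[narrow.idxmax(), "unit00"] = 1.0  # one dedicated channel
pop_matrix = of.ResponseMatrix(values=population, scale_state="sfr-reset")
pk = of.population_kurtosis(pop_matrix, narrow.idxmax(), min_units=12)
print(f"\npopulation kurtosis of the dedicated ligand across 12 units: {pk:.2f}")
print("-> a high positive PK marks an odorant that drives few units "
      "strongly, the signature of a candidate labeled-line channel")

curve = of.tuning_curve(broad.head(7))
print("\nbell arrangement of a 7-odorant profile (strongest central):")
print(curve.to_string(index=False))
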