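"""Sweep model hyperparameters and compare validation performance.

Trains the network on a single fixed fold for each setting of one
hyperparameter axis (here: channel width and optimizer) and reports the
best validation loss reached.  The full grids mirror the published
parametric study (kernel triples {1,3,5,7}^3, channels {4,...,64}, 1-4
residual blocks, SGD/RMSprop/Adam); this example uses a reduced dataset so
it finishes in about a minute.
"""

from gaitbalance import ModelConfig, SimulationConfig, generate_dataset
from gaitbalance.evaluation import hyperparameter_sweep

dataset = generate_dataset(SimulationConfig(n_subjects=4, n_trials=3, seed=5))
base = ModelConfig(n_blocks=1, max_epochs=150, patience=20, seed=5)

for parameter, values in [("channels", [4, 16, 64]),
                          ("optimizer", ["sgd", "rmsprop", "adam"])]:
    report = hyperparameter_sweep(dataset, parameter, values, base)
    print(f"\nsweep over {parameter}:")
    print(report.to_frame().to_string(index=False))
    print("best:", report.best())
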