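import numpy as np


def random_spd_matrix(rng, d, scale=1.0):
    A = rng.standard_normal((d, d))
    return scale * (A @ A.T + d * np.eye(d))
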