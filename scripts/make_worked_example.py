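"""Regenerate the committed worked-example golden file.

All numbers are produced by pure-Python double loops and exact summation,
independent of the package implementation, so the golden file can serve as
an external reference for the vectorised code paths.
"""
import json, math

SIGMA = 40.0
ETA = 0.1
T = 10.0

def kappa(a, b):
    d = abs(a - b)
    return math.exp(-d*d/(2*SIGMA*SIGMA))

def stip(a, b):
    return sum(kappa(x, y) for x in a for y in b)

def gram(p, q):
    return [[stip(pi, qj) for qj in q] for pi in p]

def matsub(a, b):
    return [[x - y for x, y in zip(ra, rb)] for ra, rb in zip(a, b)]

def scal(c, a):
    return [[c*x for x in r] for r in a]

def tmul(m, a):  # m^T @ a
    rows, cols = len(m[0]), len(a[0])
    return [[sum(m[k][i]*a[k][j] for k in range(len(m))) for j in range(cols)]
            for i in range(rows)]

inputs  = [[1.0, 4.0, 7.0], [2.0, 5.0], [0.0]]
hidden  = [[0.0, 3.0], [2.0, 5.0, 8.0], [], [6.0]]
actual  = [[1.0, 6.0], [4.0]]
desired = [[0.0, 5.0], [3.0, 9.0]]

w1 = [[0.5, -0.3, 0.8], [-0.2, 0.7, 0.1], [0.9, 0.4, -0.6], [0.3, -0.5, 0.2]]
w2 = [[0.6, -0.4, 0.2, 0.7], [-0.1, 0.5, -0.8, 0.3]]
b1 = [[-0.7, 0.2, 0.4], [0.5, -0.9, 0.3], [0.1, 0.6, -0.2], [-0.4, 0.8, 0.5]]
b2 = [[0.3, 0.9, -0.5, 0.1], [-0.6, 0.2, 0.7, -0.3]]
ba1 = [[0.4, -0.2, 0.6, -0.9], [0.8, 0.1, -0.3, 0.5]]

Fah = gram(actual, hidden)
Fdh = gram(desired, hidden)
Fai = gram(actual, inputs)
Fdi = gram(desired, inputs)
err_h = matsub(Fah, Fdh)
err_i = matsub(Fai, Fdi)
delta_w2 = scal(-ETA, err_h)
delta_w1_bp = scal(-ETA, tmul(w2, err_i))
delta_w1_fa = scal(-ETA, tmul(b2, err_i))
delta_w1_ba = scal(-ETA, tmul(ba1, err_i))
rkhs = 0.5*sum(stip(a, a) - 2*stip(a, d) + stip(d, d)
               for a, d in zip(actual, desired))

out = {
    "interval_end": T, "kernel_sigma": SIGMA, "eta": ETA,
    "inputs": inputs, "hidden": hidden, "actual": actual, "desired": desired,
    "w1": w1, "w2": w2, "b1": b1, "b2": b2, "ba1": ba1,
    "golden": {
        "stip_actual_hidden": Fah, "stip_desired_hidden": Fdh,
        "stip_actual_inputs": Fai, "stip_desired_inputs": Fdi,
        "delta_w2": delta_w2, "delta_w1_bp": delta_w1_bp,
        "delta_w1_fa": delta_w1_fa, "delta_w1_ba": delta_w1_ba,
        "rkhs_error": [[rkhs]],
    },
}
with open("src/stipnet/data/worked_example.json", "w") as fh:
    json.dump(out, fh, indent=1)
print("rkhs_error =", rkhs)
print("delta_w2[0] =", delta_w2[0])
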