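# Representative near-infrared (~690-800 nm) tissue optical properties.
# mu_a, mu_s in 1/mm.  Scattering is expressed in similarity-reduced form
# (g = 0 with mu_s set to the reduced scattering coefficient mu_s'), which
# leaves continuous-wave fluence distributions unchanged while keeping
# desk-scale simulations fast.  Values follow the ranges commonly used for
# scalp, skull, CSF and brain in diffuse-optics head modeling.
skin: {mu_a: 0.0159, mu_s: 0.80, g: 0.0, n: 1.37}
skull: {mu_a: 0.0101, mu_s: 1.00, g: 0.0, n: 1.37}
CSF: {mu_a: 0.0004, mu_s: 0.01, g: 0.0, n: 1.37}
GM: {mu_a: 0.0186, mu_s: 1.10, g: 0.0, n: 1.37}
WM: {mu_a: 0.0186, mu_s: 1.25, g: 0.0, n: 1.37}
NMA: {mu_a: 0.0186, mu_s: 1.10, g: 0.0, n: 1.37}
other-brain: {mu_a: 0.0186, mu_s: 1.10, g: 0.0, n: 1.37}
eyes: {mu_a: 0.0040, mu_s: 0.10, g: 0.0, n: 1.37}
other-inside-skull: {mu_a: 0.0160, mu_s: 0.90, g: 0.0, n: 1.37}
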