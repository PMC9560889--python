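"""Coiflet analysis filter banks (orthonormal, lowpass/scaling coefficients).

Highpass filters are derived by the standard quadrature-mirror relation
g[n] = (-1)**n * h[L-1-n], so only the lowpass taps are tabulated.
"""

COIFLET_DEC_LO = {
    "coif1": (
        -0.015655728135791993,
        -0.07273261951252645,
        0.3848648468648578,
        0.8525720202116004,
        0.3378976624574818,
        -0.07273261951252645,
    ),
    "coif2": (
        -0.000720549445520347,
        -0.0018232088709110323,
        0.005611434819368834,
        0.02368017194684777,
        -0.05943441864643109,
        -0.07648859907828076,
        0.4170051844232391,
        0.8127236354494135,
        0.3861100668227629,
        -0.0673725547237256,
        -0.04146493678687178,
        0.01638733646320364,
    ),
    "coif3": (
        -3.459977319727278e-05,
        -7.0983302506379e-05,
        0.0004662169598204029,
        0.0011175187708306303,
        -0.0025745176881367972,
        -0.009007976136730624,
        0.015880544863669452,
        0.03455502757329774,
        -0.08230192710629983,
        -0.07179982161915484,
        0.42848347637737,
        0.7937772226260872,
        0.40517690240911824,
        -0.06112339000297255,
        -0.06577191128146936,
        0.023452696142077168,
        0.007782596425672746,
        -0.003793512864380802,
    ),
    "coif4": (
        -1.7849909144933469e-06,
        -3.259647940030751e-06,
        3.1229861599195265e-05,
        6.233885431278719e-05,
        -0.0002599743371222568,
        -0.0005890202246332165,
        0.0012665610789256603,
        0.0037514346971460866,
        -0.0056582838001308835,
        -0.015211728187697211,
        0.02508225333794961,
        0.03933442260558915,
        -0.09622042453595264,
        -0.06662747236681717,
        0.43438603311435653,
        0.7822389344242826,
        0.41530842700068227,
        -0.05607731960356926,
        -0.08126671024919373,
        0.02668230466960483,
        0.01606894713157503,
        -0.007346167936268051,
        -0.001629492425226786,
        0.000892313902537003,
    ),
    "coif5": (
        -9.604010112767894e-08,
        -1.6237995172048338e-07,
        2.0612203985788783e-06,
        3.7007277113394796e-06,
        -2.1270221672515614e-05,
        -4.12198619242655e-05,
        0.00014035632812373243,
        0.0003018579416682448,
        -0.0006375589261258812,
        -0.0016616273039298788,
        0.0024315754425382886,
        0.006761520220620417,
        -0.009159507338676163,
        -0.019758391600965465,
        0.032674799467057355,
        0.041287530472117834,
        -0.10556315130733723,
        -0.06203775157498196,
        0.4379823066591634,
        0.7742936228603274,
        0.42157126673075435,
        -0.052046670253554764,
        -0.09192158806008609,
        0.028169744270532353,
        0.023408322118927783,
        -0.010131584846900276,
        -0.00415931262757864,
        0.0021782943778456947,
        0.0003585777411617577,
        -0.000212081862067494,
    ),
}
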