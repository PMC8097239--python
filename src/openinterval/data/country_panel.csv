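# Power-model parameters (a, magnitude of b as printed), TFR, GFR and reported
# fit R2 for the latest survey in each of 75 countries, transcribed from a
# published DHS-based compilation. Parenthesized b values in the source denote
# negative slopes; the magnitude is stored here and the sign applied on load.
survey_label,a,b_printed,tfr,gfr,r2
Afghanistan 2015,0.440,1.426,5.3,175,0.956
Albania 2017-18,0.082,0.283,1.8,57,0.431
Angola 2015-16,0.603,1.678,6.2,216,0.970
Armenia 2015-16,0.121,0.538,1.7,64,0.968
Azerbaijan 2006,0.089,0.328,2.0,66,0.600
Bangladesh 2014,0.165,0.630,2.3,90,0.943
Benin 2017-18,0.673,0.174,5.7,197,0.912
Bolivia 2008,0.281,0.963,3.5,121,0.913
Brazil 1996,0.147,0.538,2.5,89,0.931
Burkina Faso 2010,0.581,1.616,6.0,206,0.961
Burundi 2016-17,0.748,1.846,5.5,180,0.923
Cambodia 2014,0.215,0.779,2.7,98,0.953
Cameroon 2011,0.426,1.385,5.1,180,0.977
Central African Republic 1994-95,0.428,1.388,5.1,183,0.966
Chad 2014-15,0.597,1.697,6.4,230,0.954
Colombia 2015,0.129,0.495,2.0,70,0.947
Comoros 2012,0.392,1.283,4.3,142,0.981
Congo 2011-12,0.471,1.453,5.1,182,0.988
Congo Democratic Republic 2013-14,0.535,1.641,6.6,225,0.982
Cote d'Ivoire 2011-12,0.469,1.423,5.0,174,0.973
Dominican Republic 2013,0.172,0.696,2.5,89,0.977
Egypt 2014,0.271,0.971,3.5,127,0.985
Ethiopia 2016,0.544,1.506,4.6,156,0.925
Gabon 2012,0.359,1.225,4.1,144,0.947
Gambia 2013,0.561,1.635,5.6,185,0.974
Ghana 2014,0.386,1.242,4.2,143,0.977
Guatemala 2014-15,0.254,0.904,3.1,112,0.981
Guinea 2018,0.543,0.152,4.8,165,0.930
Guyana 2009,0.152,0.602,2.8,94,0.914
Haiti 2016-17,0.404,0.124,3.0,101,0.861
Honduras 2011-12,0.235,0.844,2.9,107,0.974
India 2015-16,0.125,0.520,2.2,81,0.968
Indonesia 2017,0.189,0.737,2.4,80,0.794
Jordan 2017-18,0.309,1.065,2.7,90,0.892
Kazakhstan 1999,0.105,0.351,2.0,67,0.819
Kenya 2014,0.400,1.236,3.9,141,0.929
Kyrgyz Republic 2012,0.257,0.968,3.6,125,0.985
Lesotho 2014,0.312,1.050,3.3,118,0.929
Liberia 2013,0.418,1.282,4.7,168,0.935
Madagascar 2008-09,0.396,1.255,4.8,168,0.958
Malawi 2015-16,0.701,1.691,4.4,158,0.914
Maldives 2016-17,0.245,0.904,2.1,78,0.811
Mali 2012-13,0.559,1.590,6.1,214,0.967
Moldova 2005,0.078,0.294,1.7,55,0.747
Morocco 2003-04,0.262,0.912,2.5,81,0.941
Mozambique 2011,0.458,1.464,5.9,206,0.975
Myanmar 2015-16,0.198,0.723,2.3,77,0.932
Namibia 2013,0.305,1.039,3.6,125,0.948
Nepal 2016,0.146,0.573,2.3,88,0.970
Nicaragua 2001,0.258,0.910,3.2,117,0.906
Niger 2012,0.699,1.881,7.6,269,0.967
Nigeria 2018,0.559,1.579,5.3,182,0.940
Pakistan 2017-18,0.372,1.217,3.6,124,0.942
Papua New Guinea 2017,0.450,1.350,4.2,142,0.895
Paraguay 1990,0.395,1.255,4.7,160,0.943
Peru 2012,0.198,0.746,2.6,86,0.911
Philippines 2017,0.242,0.888,2.7,89,0.877
Rwanda 2014-15,0.646,1.629,4.2,142,0.832
Sao Tome and Principe 2008-09,0.457,1.392,4.9,164,0.952
Senegal 2017,0.764,1.792,4.6,152,0.917
Sierra Leone 2013,0.489,1.428,4.9,169,0.938
South Africa 2016,0.210,0.809,2.6,94,0.765
Swaziland 2006-07,0.307,1.055,3.8,137,0.946
Tajikistan 2017,0.281,1.018,3.8,141,0.939
Tanzania 2015-16,0.482,1.437,5.2,178,0.962
Timor-Leste 2016,0.384,1.197,4.2,136,0.913
Togo 2013-14,0.479,1.425,4.8,163,0.965
Turkey 2013,0.158,0.637,2.3,78,0.824
Uganda 2016,0.559,1.568,5.4,189,0.966
Ukraine 2007,0.066,0.254,1.2,39,0.798
Uzbekistan 1996,0.259,0.900,3.3,123,0.959
Viet Nam 2002,0.106,0.341,1.9,60,0.753
Yemen 2013,0.454,1.373,4.4,146,0.959
Zambia 2018,0.664,1.675,4.7,163,0.906
Zimbabwe 2015,0.470,1.379,4.0,144,0.931
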