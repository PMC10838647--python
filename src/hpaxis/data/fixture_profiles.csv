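individual_id,sampling_class,time_min,gc_value,gr_expression
ind000,baseline,1.3168548802403461,10.132907635519656,3.0578128618170166
ind000,stress_induced,25.32595021522904,27.737658959878097,3.0578128618170166
ind000,post_dex,60.06264574915659,4.4000248115177305,3.0578128618170166
ind000,post_acth,100.0,107.58874678884827,3.0578128618170166
ind001,baseline,2.5754713122669917,5.117780257962063,4.87250726804422
ind001,stress_induced,24.252983511963176,12.669994057057124,4.87250726804422
ind001,post_dex,74.71637988079334,2.7817850621094955,4.87250726804422
ind001,post_acth,100.0,70.13607862610634,4.87250726804422
ind002,baseline,0.4604225133843467,4.470892085342561,9.105212863633572
ind002,stress_induced,29.92259229487619,5.768141155713732,9.105212863633572
ind002,post_dex,63.646635656979065,0.8349097645315552,9.105212863633572
ind002,post_acth,100.0,79.26236822773497,9.105212863633572
ind003,baseline,0.2606491658195592,4.594555519777347,6.524646758178617
ind003,stress_induced,24.68210715073851,15.421286662003201,6.524646758178617
ind003,post_dex,76.5797839985777,3.6300493358904404,6.524646758178617
ind003,post_acth,100.0,84.45297417945883,6.524646758178617
ind004,baseline,2.6072745335475345,4.373776897108457,7.12912008510252
ind004,stress_induced,29.764165742940587,6.630985780372042,7.12912008510252
ind004,post_dex,76.83427314893135,1.3444893508097848,7.12912008510252
ind004,post_acth,100.0,89.83424098759312,7.12912008510252
ind005,baseline,1.1115252893120657,2.0929449496660366,17.937286535484482
ind005,stress_induced,24.8266943701385,3.2308818885265715,17.937286535484482
ind005,post_dex,61.843630936965596,0.767499652012236,17.937286535484482
ind005,post_acth,100.0,62.64933829933016,17.937286535484482
ind006,baseline,1.6096987102539366,8.89695359866778,3.454472749305654
ind006,stress_induced,27.332316511708388,24.486445470374782,3.454472749305654
ind006,post_dex,68.97821577824244,6.953198413416982,3.454472749305654
ind006,post_acth,100.0,92.34812262899574,3.454472749305654
ind007,baseline,2.8420788098659258,5.4687778664188444,13.993249330164709
ind007,stress_induced,27.510338363593167,6.475288538234818,13.993249330164709
ind007,post_dex,69.44096919744472,0.6107067213268828,13.993249330164709
ind007,post_acth,100.0,65.25715374621711,13.993249330164709
ind008,baseline,2.2390134097109673,10.042868600355114,2.6519133526485223
ind008,stress_induced,28.55399877837578,24.198504472814793,2.6519133526485223
ind008,post_dex,65.87003116272419,5.478590790535539,2.6519133526485223
ind008,post_acth,100.0,105.42241985261921,2.6519133526485223
ind009,baseline,2.4264921076868733,5.302178747789136,7.381887367984134
ind009,stress_induced,28.870869741717364,8.366537907867317,7.381887367984134
ind009,post_dex,60.49666422534056,1.0269645539448742,7.381887367984134
ind009,post_acth,100.0,77.0714623316938,7.381887367984134
ind010,baseline,1.8383570411319194,6.384057432524814,4.14328691616084
ind010,stress_induced,22.803489516290337,15.976494106190986,4.14328691616084
ind010,post_dex,69.04263453148126,3.8760958197141755,4.14328691616084
ind010,post_acth,100.0,84.29284092948907,4.14328691616084
ind011,baseline,2.965903690285984,4.40375838169904,10.422143741977548
ind011,stress_induced,20.059781688730144,10.483630157655488,10.422143741977548
ind011,post_dex,64.02576571152565,0.734484757078087,10.422143741977548
ind011,post_acth,100.0,60.0654189045341,10.422143741977548
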