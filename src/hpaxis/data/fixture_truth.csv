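individual_id,G_tot,b,gr_expression,gc_true_baseline,gc_true_stress_induced,gc_true_post_dex,gc_true_post_acth
ind000,2.8126803023596496,5.0,3.0578128618170166,8.718319270979574,25.3217763957348,4.197305232459287,98.47564040214554
ind001,6.184455913193311,5.0,4.87250726804422,5.591115365279346,12.609232287961293,3.269813038805403,84.18002953163261
ind002,8.514258581374948,5.0,9.105212863633572,4.099676091457009,5.8837525594274895,0.7589874393960689,78.62340443478126
ind003,6.448540556215979,5.0,6.524646758178617,4.987624149079784,11.61169654477437,3.1799198026873348,83.43493254590919
ind004,9.022987039441613,5.0,7.12912008510252,4.385849726734432,5.651217508427412,1.395282530755798,77.54543324649765
ind005,23.756386462178277,5.0,17.937286535484482,1.970425565370398,3.7046330764546656,0.716210032264419,56.321032895910975
ind006,2.983782571471285,5.0,3.454472749305654,8.466981136942115,22.352301573230175,6.092392741945895,97.4701979756483
ind007,9.378151547415692,5.0,13.993249330164709,4.389424985970354,6.4035152701412255,0.564771629202345,76.77882506938532
ind008,2.731112923720182,5.0,2.6519133526485223,9.125116937218733,22.62959827945033,5.835973904858244,98.97187763320976
ind009,7.057831028495171,5.0,7.381887367984134,5.066661247361025,7.608899680228424,0.9609633176414843,81.85970394201819
ind010,4.710014267654818,5.0,4.14328691616084,6.3808710802443125,19.0208549137085,3.887097049739921,89.1852357054134
ind011,11.213043374043762,5.0,10.422143741977548,3.9781439557954936,9.215313404256465,0.6924062976017925,72.61259916657751
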