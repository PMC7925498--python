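analyte,class,rt_min,precursor_mz,product_mz,role,dwell_ms,dp_v,ep_v,ce,cxp_v,molar_mass_g_mol
792,ISD,20.5,792.0,96.0,quantifier,150,-155,-10,-128,-15,794
792,ISD,20.5,792.0,58.0,qualifier1,150,-155,-10,-130,-1,794
792,ISD,20.5,792.0,80.0,qualifier2,150,-155,-10,-128,-3,794
555,SQMG,9.23,555.0,80.0,quantifier,150,-130,-10,-100,-3,555
555,SQMG,9.23,555.0,94.0,qualifier1,150,-130,-10,-80,-5,555
555,SQMG,9.23,555.0,224.0,qualifier2,150,-130,-10,-64,-15,555
765,SQDG,19.7,765.0,80.0,quantifier,150,-110,-10,-120,-11,765
765,SQDG,19.7,765.0,224.0,qualifier1,150,-110,-10,-64,-15,765
765,SQDG,19.7,765.0,94.0,qualifier2,150,-110,-10,-112,-5,765
787,SQDG,15.4,787.3,80.0,quantifier,150,-155,-10,-112,-11,787
787,SQDG,15.4,787.3,224.0,qualifier1,150,-155,-10,-64,-1,787
787,SQDG,15.4,787.3,164.0,qualifier2,150,-155,-10,-11,-11,787
789,SQDG,17.4,789.2,80.8,quantifier,150,-165,-10,-130,-1,789
789,SQDG,17.4,789.2,224.7,qualifier1,150,-165,-10,-64,-17,789
789,SQDG,17.4,789.2,164.7,qualifier2,150,-165,-10,-14,-11,789
791,SQDG,11.7,791.0,81.0,quantifier,150,-160,-10,-104,-3,791
791,SQDG,11.7,791.0,225.0,qualifier1,150,-160,-10,-64,-5,791
791,SQDG,11.7,791.0,165.0,qualifier2,150,-160,-10,-80,-1,791
793,SQDG,25.7,793.0,80.8,quantifier,150,-135,-10,-130,-9,793
793,SQDG,25.7,793.0,224.8,qualifier1,150,-135,-10,-17,-17,793
793,SQDG,25.7,793.0,79.9,qualifier2,150,-135,-10,-1,-1,793
801,SQDG,16.6,801.3,81.0,quantifier,150,-150,-10,-130,-11,801
801,SQDG,16.6,801.3,152.9,qualifier1,150,-150,-10,-70,-9,801
801,SQDG,16.6,801.3,224.9,qualifier2,150,-150,-10,-62,-15,801
803,SQDG,18.9,803.4,80.6,quantifier,150,-185,-10,-128,-3,803
803,SQDG,18.9,803.4,224.8,qualifier1,150,-185,-10,-64,-17,803
803,SQDG,18.9,803.4,164.5,qualifier2,150,-185,-10,-80,-11,803
805,SQDG,23.1,805.0,81.0,quantifier,150,-65,-10,-114,-3,805
805,SQDG,23.1,805.0,80.0,qualifier1,150,-65,-10,-126,-1,805
805,SQDG,23.1,805.0,224.0,qualifier2,150,-65,-10,-68,-17,805
807,SQDG,29.7,807.2,80.6,quantifier,150,-130,-10,-126,-1,807
807,SQDG,29.7,807.2,224.9,qualifier1,150,-130,-10,-66,-11,807
807,SQDG,29.7,807.2,94.8,qualifier2,150,-130,-10,-108,-3,807
813,SQDG,15.7,813.3,80.9,quantifier,150,-160,-10,-130,-1,813
813,SQDG,15.7,813.3,152.7,qualifier1,150,-160,-10,-72,-13,813
813,SQDG,15.7,813.3,94.7,qualifier2,150,-160,-10,-126,-1,813
815,SQDG,18.4,815.4,80.9,quantifier,150,-205,-10,-118,-3,815
815,SQDG,18.4,815.4,152.7,qualifier1,150,-205,-10,-64,-15,815
815,SQDG,18.4,815.4,94.7,qualifier2,150,-205,-10,-106,-5,815
817,SQDG,21.3,817.0,81.0,quantifier,150,-230,-10,-120,-11,817
817,SQDG,21.3,817.0,225.0,qualifier1,150,-230,-10,-66,-17,817
817,SQDG,21.3,817.0,165.0,qualifier2,150,-230,-10,-72,-9,817
819,SQDG,26.1,819.3,80.8,quantifier,150,-150,-10,-116,-1,819
819,SQDG,26.1,819.3,225.1,qualifier1,150,-150,-10,-68,-3,819
819,SQDG,26.1,819.3,164.7,qualifier2,150,-150,-10,-72,-13,819
821,SQDG,36.0,821.5,80.8,quantifier,150,-140,-10,-130,-1,821
821,SQDG,36.0,821.5,225.1,qualifier1,150,-140,-10,-72,-1,821
821,SQDG,36.0,821.5,95.0,qualifier2,150,-140,-10,-120,-5,821
837,SQDG,14.6,837.2,80.9,quantifier,150,-80,-10,-124,-3,837
837,SQDG,14.6,837.2,224.7,qualifier1,150,-80,-10,-66,-15,837
837,SQDG,14.6,837.2,165.1,qualifier2,150,-80,-10,-74,-1,837
839,SQDG,16.3,839.3,80.0,quantifier,150,-110,-10,-120,-5,839
839,SQDG,16.3,839.3,224.0,qualifier1,150,-110,-10,-62,-17,839
839,SQDG,16.3,839.3,164.0,qualifier2,150,-110,-10,-76,-11,839
841,SQDG,18.6,841.3,80.9,quantifier,150,-200,-10,-124,-11,841
841,SQDG,18.6,841.3,224.7,qualifier1,150,-200,-10,-72,-15,841
841,SQDG,18.6,841.3,164.7,qualifier2,150,-200,-10,-82,-9,841
843,SQDG,22.7,843.3,80.9,quantifier,150,-170,-10,-118,-3,843
843,SQDG,22.7,843.3,224.9,qualifier1,150,-170,-10,-68,-17,843
843,SQDG,22.7,843.3,94.7,qualifier2,150,-170,-10,-110,-3,843
845,SQDG,28.0,845.4,80.9,quantifier,150,-175,-10,-118,-3,845
845,SQDG,28.0,845.4,224.6,qualifier1,150,-175,-10,-70,-11,845
845,SQDG,28.0,845.4,94.8,qualifier2,150,-175,-10,-120,-15,845
847,SQDG,10.4,847.3,81.1,quantifier,150,-170,-10,-122,-11,847
847,SQDG,10.4,847.3,224.7,qualifier1,150,-170,-10,-70,-15,847
847,SQDG,10.4,847.3,95.0,qualifier2,150,-170,-10,-110,-1,847
833,SQDG,13.0,833.5,81.1,quantifier,150,-100,-10,-124,-3,833
833,SQDG,13.0,833.5,224.8,qualifier1,150,-100,-10,-66,-19,833
833,SQDG,13.0,833.5,165.0,qualifier2,150,-100,-10,-75,-11,833
849,SQDG,11.9,849.4,80.8,quantifier,150,-160,-10,-130,-11,849
849,SQDG,11.9,849.4,224.7,qualifier1,150,-160,-10,-72,-3,849
849,SQDG,11.9,849.4,94.6,qualifier2,150,-160,-10,-130,-3,849
855,SQDG,11.0,855.0,80.0,quantifier,150,-145,-10,-128,-1,855
855,SQDG,11.0,855.0,224.0,qualifier1,150,-145,-10,-74,-11,855
855,SQDG,11.0,855.0,164.0,qualifier2,150,-145,-10,-80,-9,855
867,SQDG,,867.0,80.0,quantifier,150,-175,-10,-128,-3,867
867,SQDG,,867.0,224.0,qualifier1,150,-175,-10,-78,-15,867
867,SQDG,,867.0,164.0,qualifier2,150,-175,-10,-86,-1,867
871,SQDG,,871.0,80.0,quantifier,150,-195,-10,-126,-3,871
871,SQDG,,871.0,224.0,qualifier1,150,-195,-10,-72,-17,871
871,SQDG,,871.0,164.0,qualifier2,150,-195,-10,-80,-7,871
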