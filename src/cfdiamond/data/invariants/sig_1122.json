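{"signature":[1,1,2,2],"reduced":[["m",0],["m",1],["m",2],["m",3],["m",4],["m",5],["u1",6],["u2",6],["m",7]],"provenance":"numeric-interpolation","max_degree":2,"polys":[[[1,1,[0]],[-3,1,[1,4]],[3,1,[1,8]],[-3,1,[2,5]]],[[1,1,[1]],[-1,2,[5]],[-3,2,[1,7]],[-1,1,[3,6]],[-1,2,[3,7]],[1,2,[5,6]],[1,1,[5,7]]],[[1,1,[2]],[1,1,[4]],[-1,1,[8]],[-2,1,[2,6]],[-1,1,[2,7]]],[[1,1,[3]],[-1,1,[5]],[-1,1,[3,6]],[-1,2,[3,7]],[1,2,[5,6]],[1,1,[5,7]]],[[1,1,[0,6]],[-2,1,[1,4]],[2,1,[1,8]],[-1,1,[2,3]]],[[1,1,[0,7]],[-2,1,[1,4]],[2,1,[1,8]],[2,1,[2,3]],[-3,1,[2,5]]],[[1,1,[1,2]],[-1,1,[1,4]],[1,1,[1,8]],[-1,1,[2,5]]],[[1,1,[1,6]],[-1,1,[1,7]],[-1,1,[3,6]],[-1,2,[3,7]],[1,2,[5,6]],[1,1,[5,7]]]],"checksum":"dcf56ecd76496b368b4b510beed293b875ec4a845d1fafe619d4b6a99b588186"}
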