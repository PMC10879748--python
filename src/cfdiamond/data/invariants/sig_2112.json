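{"signature":[2,1,1,2],"reduced":[["m",0],["m",1],["m",2],["u1",3],["u2",3],["m",4],["m",5],["m",6],["m",7]],"provenance":"numeric-interpolation","max_degree":2,"polys":[[[1,1,[0]],[-1,2,[2]],[-3,2,[0,4]],[-1,1,[1,3]],[-1,2,[1,4]],[1,2,[2,3]],[1,1,[2,4]]],[[1,1,[1]],[-1,1,[2]],[-1,1,[1,3]],[-1,2,[1,4]],[1,2,[2,3]],[1,1,[2,4]]],[[1,1,[0,3]],[-1,1,[0,4]],[-1,1,[1,3]],[-1,2,[1,4]],[1,2,[2,3]],[1,1,[2,4]]],[[1,1,[0]],[-1,2,[1]],[-3,2,[0,3]],[1,1,[1,3]],[1,2,[1,4]],[-1,2,[2,3]],[-1,1,[2,4]]]],"checksum":"36a2b7de7a25973134f71b47552461c2abda3a5473350c2a5dc44d5fe3c5904d"}
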